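import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from sepmap.classes import NODATA_CODE, PatchClass
from sepmap.classifier import (
    CalibrationError,
    ClassifierSpec,
    DecisionNode,
    burn_overlays,
    classify,
    derive_tree,
    detect_built_patches,
    tree_from_dict,
    tree_to_dict,
)
from sepmap.grid import GridGeometry, Raster
from sepmap.indices import ClassSignature, SeparabilityMatrix
from sepmap.landscape import (
    LayoutConfig,
    SpectralSignatureModel,
    generate_landscape,
    sample_calibration_pixels,
)
from sepmap.pipeline import build_classifier_spec
from sepmap.indices import add_derived_layers


def _grid(n=6, pixel=30.0):
    return GridGeometry(0.0, n * pixel, pixel, (n, n))


class TestBurnOverlays:
    def test_square_covering_four_centers(self):
        grid = _grid(6)
        # centers at 15+30k; a box (0,120)-(60,180) covers 4 centers
        poly = box(0, 120, 60, 180)
        out = burn_overlays(grid, [(poly, PatchClass.HOMESTEAD)])
        assert (out.data == int(PatchClass.HOMESTEAD)).sum() == 4

    def test_later_overlay_wins(self):
        grid = _grid(6)
        poly = box(0, 120, 60, 180)
        out = burn_overlays(
            grid,
            [(poly, PatchClass.DEPRESSION), (poly, PatchClass.URBAN)],
        )
        assert (out.data == int(PatchClass.URBAN)).sum() == 4
        assert (out.data == int(PatchClass.DEPRESSION)).sum() == 0

    def test_polygon_outside_extent(self):
        grid = _grid(6)
        out = burn_overlays(grid, [(box(1e6, 1e6, 1e6 + 50, 1e6 + 50), PatchClass.URBAN)])
        assert np.all(out.data == NODATA_CODE)

    def test_empty_overlay_list_is_valid(self):
        out = burn_overlays(_grid(4), [])
        assert np.all(out.data == NODATA_CODE)


class TestDetectBuiltPatches:
    def _brightness(self, n=30):
        grid = _grid(n)
        return grid, np.zeros((n, n))

    def test_single_block_becomes_homestead(self):
        grid, data = self._brightness()
        data[5:8, 5:8] = 1.0
        out = detect_built_patches(
            Raster(data, grid), size_limits=(2, 20), threshold=0.5
        )
        assert len(out["homestead"]) == 1 and len(out["urban"]) == 0
        assert out["homestead"][0].area == pytest.approx(9 * 30.0**2)

    def test_strict_threshold_boundary(self):
        grid, data = self._brightness()
        data[:] = 0.5
        out = detect_built_patches(Raster(data, grid), (1, 100), threshold=0.5)
        assert out["homestead"] == [] and out["urban"] == []

    def test_size_rule_with_village(self):
        grid, data = self._brightness(40)
        data[2:5, 2:5] = 1.0  # 9 px
        data[10:35, 10:30] = 1.0  # 500 px
        x, y = grid.rowcol_to_center(20, 20)
        villages = pd.DataFrame({"x": [float(x)], "y": [float(y)], "village_id": [0]})
        out = detect_built_patches(
            Raster(data, grid), (2, 100), village_points=villages, threshold=0.5
        )
        assert len(out["homestead"]) == 1
        assert out["homestead"][0].area == pytest.approx(9 * 900.0)
        assert len(out["urban"]) == 1
        assert out["urban"][0].area == pytest.approx(500 * 900.0)

    def test_tiny_components_dropped(self):
        grid, data = self._brightness()
        data[3, 3] = 1.0
        out = detect_built_patches(Raster(data, grid), (2, 20), threshold=0.5)
        assert out["homestead"] == [] and out["urban"] == []


def _sig(code, layer, mean, std=1.0, n=10):
    return ClassSignature(class_code=code, layer=layer, n=n, mean=mean, std=std)


class TestDeriveTree:
    def test_two_class_midpoint(self):
        sigs = [_sig(1, "x", 0.0), _sig(2, "x", 10.0)]
        tree = derive_tree(sigs, SeparabilityMatrix(sigs), [1, 2], m_threshold=1.0)
        assert isinstance(tree, DecisionNode)
        assert tree.threshold == 5.0
        assert tree.true_branch == 1 and tree.false_branch == 2
        assert tree.operator == "<="  # class 1 mean below the midpoint

    def test_inseparable_classes_raise(self):
        sigs = [_sig(1, "x", 5.0), _sig(2, "x", 5.0)]
        with pytest.raises(CalibrationError):
            derive_tree(sigs, SeparabilityMatrix(sigs), [1, 2])

    def test_error_names_class_pair(self):
        sigs = [_sig(1, "x", 0.0), _sig(2, "x", 0.5)]  # M = 0.25 < 1
        with pytest.raises(CalibrationError, match="bare_soil.*depression"):
            derive_tree(sigs, SeparabilityMatrix(sigs), [1, 2])

    def test_three_classes_two_internal_nodes(self):
        sigs = [_sig(1, "x", 0.0), _sig(2, "x", 10.0), _sig(3, "x", 20.0)]
        tree = derive_tree(sigs, SeparabilityMatrix(sigs), [1, 2, 3])
        n_nodes = 0
        node = tree
        while isinstance(node, DecisionNode):
            n_nodes += 1
            node = node.false_branch
        assert n_nodes == 2
        assert node == 3  # last class is the default leaf

    def test_picks_most_separable_layer(self):
        sigs = [
            _sig(1, "good", 0.0, 0.5),
            _sig(2, "good", 10.0, 0.5),
            _sig(1, "bad", 0.0, 5.0),
            _sig(2, "bad", 1.0, 5.0),
        ]
        tree = derive_tree(sigs, SeparabilityMatrix(sigs), [1, 2])
        assert tree.layer == "good"

    def test_missing_signature_rejected(self):
        sigs = [_sig(1, "x", 0.0)]
        with pytest.raises(ValueError, match="missing"):
            derive_tree(sigs, SeparabilityMatrix(sigs), [1, 2])


class TestClassify:
    def _layers(self, grid, **named):
        return {k: Raster(np.asarray(v, float), grid, nodata=np.nan) for k, v in named.items()}

    def _three_node_tree(self):
        # water if wet >= 0.5 else (forest if green >= 0.6 else field)
        return DecisionNode(
            "wet", ">=", 0.5, int(PatchClass.WATER),
            DecisionNode("green", ">=", 0.6, int(PatchClass.FOREST), int(PatchClass.FIELD)),
        )

    def test_hand_traced_pixels(self):
        grid = _grid(2)
        layers = self._layers(
            grid,
            wet=[[0.9, 0.1], [0.5, 0.2]],
            green=[[0.0, 0.7], [0.0, 0.1]],
        )
        spec = ClassifierSpec(self._three_node_tree())
        out = classify(layers, spec)
        # manual trace: (0,0) wet>=.5 -> water; (0,1) green>=.6 -> forest;
        # (1,0) wet==.5 ties to true branch -> water; (1,1) -> field
        assert out.data[0, 0] == int(PatchClass.WATER)
        assert out.data[0, 1] == int(PatchClass.FOREST)
        assert out.data[1, 0] == int(PatchClass.WATER)
        assert out.data[1, 1] == int(PatchClass.FIELD)

    def test_all_nodata_in_all_nodata_out(self):
        grid = _grid(3)
        nanarr = np.full((3, 3), np.nan)
        layers = self._layers(grid, wet=nanarr, green=nanarr)
        out = classify(layers, ClassifierSpec(self._three_node_tree()))
        assert np.all(out.data == NODATA_CODE)

    def test_missing_layer_fails_before_processing(self):
        grid = _grid(3)
        layers = self._layers(grid, wet=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="green"):
            classify(layers, ClassifierSpec(self._three_node_tree()))

    def test_overlay_pixels_never_overwritten(self):
        grid = _grid(4)
        layers = self._layers(grid, wet=np.ones((4, 4)), green=np.zeros((4, 4)))
        poly = box(0, 60, 60, 120)
        spec = ClassifierSpec(
            self._three_node_tree(), overlay_layers=[(poly, PatchClass.URBAN)]
        )
        out = classify(layers, spec)
        burned = burn_overlays(grid, spec.overlay_layers)
        urban = burned.data == int(PatchClass.URBAN)
        assert urban.sum() > 0
        assert np.all(out.data[urban] == int(PatchClass.URBAN))
        assert np.all(out.data[~urban] == int(PatchClass.WATER))

    def test_vectorized_equals_per_pixel_recursion(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            grid = GridGeometry(0, 16 * 30.0, 30.0, (16, 16))
            layers = self._layers(
                grid, a=rng.uniform(0, 1, (16, 16)), b=rng.uniform(0, 1, (16, 16))
            )
            tree = DecisionNode(
                "a", ">=", rng.uniform(0.2, 0.8), int(PatchClass.WATER),
                DecisionNode(
                    "b", "<", rng.uniform(0.2, 0.8),
                    int(PatchClass.FIELD), int(PatchClass.SHRUBLAND),
                ),
            )
            out = classify(layers, ClassifierSpec(tree))
            for r in range(16):
                for c in range(16):
                    values = {k: float(v.data[r, c]) for k, v in layers.items()}
                    assert out.data[r, c] == tree.evaluate_pixel(values)

    def test_zero_noise_recovery_is_exact(self):
        model = SpectralSignatureModel(stds=0.0)
        layout = LayoutConfig(shape=(80, 80), n_villages=3)
        truth, scene, dem = generate_landscape(model, layout, seed=13)
        add_derived_layers(scene)
        cal = sample_calibration_pixels(truth, n_per_class=20, seed=14)
        overlays = [
            (truth.depression_polygons, PatchClass.DEPRESSION),
            (truth.homestead_polygons, PatchClass.HOMESTEAD),
            (truth.urban_polygons, PatchClass.URBAN),
        ]
        spec, _ = build_classifier_spec(scene, dem, cal, overlays, {})
        out = classify(dict(scene.layers), spec, dem=dem)
        assert np.array_equal(out.data, truth.patch_raster.data)

    def test_accuracy_non_increasing_in_noise(self):
        layout = LayoutConfig(shape=(80, 80), n_villages=3)
        accs = []
        for std in (0.0, 0.02, 0.08, 0.2):
            model = SpectralSignatureModel(stds=std)
            truth, scene, dem = generate_landscape(model, layout, seed=21)
            add_derived_layers(scene)
            cal = sample_calibration_pixels(truth, n_per_class=25, seed=22)
            overlays = [
                (truth.depression_polygons, PatchClass.DEPRESSION),
                (truth.homestead_polygons, PatchClass.HOMESTEAD),
                (truth.urban_polygons, PatchClass.URBAN),
            ]
            spec, _ = build_classifier_spec(scene, dem, cal, overlays, {"m_threshold": 0.3})
            out = classify(dict(scene.layers), spec, dem=dem)
            accs.append(float(np.mean(out.data == truth.patch_raster.data)))
        assert all(a >= b - 1e-9 for a, b in zip(accs, accs[1:])), accs
        assert accs[0] == 1.0


class TestTreeSerialization:
    def test_roundtrip(self):
        tree = DecisionNode(
            "ndvi_rainy", "<=", 0.31, int(PatchClass.BARE_SOIL),
            DecisionNode("dem", ">", 305.0, int(PatchClass.SHRUBLAND), int(PatchClass.FIELD)),
        )
        again = tree_from_dict(tree_to_dict(tree))
        assert tree_to_dict(again) == tree_to_dict(tree)

    def test_leaf_labels_human_readable(self):
        d = tree_to_dict(DecisionNode("x", "<", 1.0, int(PatchClass.WATER), NODATA_CODE))
        assert d["true"] == "water" and d["false"] == "nodata"
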