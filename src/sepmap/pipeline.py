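"""Pipeline orchestration: config validation, stage sequencing, artifacts.

Stage order: synthetic landscape (or real inputs) -> derived spectral
layers -> hybrid classification -> benefit mapping -> accuracy assessment.
Every run writes its artifacts plus a provenance record (config hash, seed,
library versions) and is idempotent for a fixed config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sepmap import __version__
from sepmap.accuracy import AccuracyReport, assess
from sepmap.benefits import (
    Benefit,
    BenefitScoreTable,
    DEFAULT_SHRUB_BREAKPOINTS,
    DEFAULT_SHRUB_WEIGHTS,
    WeightRaster,
    compute_all_benefit_maps,
    heat_map,
    homestead_distance_weights,
    shrubland_area_weights,
    voronoi_territories,
)
from sepmap.classes import LEGEND, PatchClass
from sepmap.classifier import (
    ClassifierSpec,
    DEFAULT_CLASS_ORDER,
    classify,
    derive_tree,
    detect_built_patches,
    tree_from_dict,
    tree_to_dict,
)
from sepmap.grid import Raster
from sepmap.indices import (
    SeparabilityMatrix,
    add_derived_layers,
    class_signatures,
    signatures_to_frame,
)
from sepmap.io import (
    read_config,
    read_raster,
    read_survey_points,
    read_vector,
    write_json_report,
    write_raster,
    write_survey_points,
    write_table,
    write_vector,
)
from sepmap.landscape import (
    LandscapeTruth,
    LayoutConfig,
    SpectralSignatureModel,
    generate_landscape,
    sample_calibration_pixels,
    sample_transects,
)
from sepmap.points import SurveyPoints
from sepmap.scene import MultiSeasonScene

log = logging.getLogger("sepmap")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for error routing."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``from_dict`` for the key set)."""

    seed: int = 0
    output_dir: Path = Path("sepmap_out")
    synthetic: dict | None = None
    real: dict | None = None
    classifier: dict = dc_field(default_factory=dict)
    benefits: dict = dc_field(default_factory=dict)
    accuracy: dict = dc_field(default_factory=dict)
    raw: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.real is None):
            raise ValueError(
                "config must contain exactly one of 'synthetic' or 'real' inputs"
            )
        if self.real is not None:
            for key in ("scene", "dem", "points"):
                if key not in self.real:
                    raise ValueError(f"real-input config missing {key!r}")
            paths = list(self.real["scene"].values()) + [self.real["dem"], self.real["points"]]
            for ov in (self.real.get("overlays") or {}).values():
                paths.append(ov)
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"referenced input does not exist: {p}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            seed=int(d.get("seed", 0)),
            output_dir=Path(d.get("output_dir", "sepmap_out")),
            synthetic=d.get("synthetic"),
            real=d.get("real"),
            classifier=d.get("classifier") or {},
            benefits=d.get("benefits") or {},
            accuracy=d.get("accuracy") or {},
            raw=d,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(read_config(path))

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    patch_map: Raster
    benefit_maps: dict[Benefit, Raster]
    heat: Raster
    report: AccuracyReport
    truth: LandscapeTruth | None
    output_dir: Path


# -- stage helpers -----------------------------------------------------------


def build_synthetic_inputs(cfg: dict, seed: int):
    """Generate truth/scene/DEM/villages/points from the synthetic block."""
    layout_kwargs = dict(cfg.get("layout") or {})
    if "shape" in layout_kwargs:
        layout_kwargs["shape"] = tuple(layout_kwargs["shape"])
    layout = LayoutConfig(**layout_kwargs)
    sig_kwargs = dict(cfg.get("signatures") or {})
    model = SpectralSignatureModel(**sig_kwargs)
    truth, scene, dem = generate_landscape(model, layout, seed=seed)

    tcfg = dict(cfg.get("transects") or {})
    points = sample_transects(truth, seed=seed + 1, **tcfg)
    n_cal = int(cfg.get("calibration_pixels_per_class", 30))
    cal_extra = sample_calibration_pixels(truth, n_per_class=n_cal, seed=seed + 2)
    combined = SurveyPoints(
        pd.concat([points.df, cal_extra.df], ignore_index=True)
    )
    return truth, scene, dem, combined


def load_real_inputs(cfg: dict):
    """Read scene bands, DEM, overlays and survey points from files."""
    scene = MultiSeasonScene()
    for name, path in cfg["scene"].items():
        scene.add(name, read_raster(path))
    dem = read_raster(cfg["dem"])
    points = read_survey_points(cfg["points"])
    overlays = []
    for label, path in (cfg.get("overlays") or {}).items():
        geoms, _ = read_vector(path)
        overlays.append((geoms, PatchClass.from_label(label)))
    villages = None
    if cfg.get("villages"):
        geoms, props = read_vector(cfg["villages"])
        villages = pd.DataFrame(
            {
                "x": [g.x for g in geoms],
                "y": [g.y for g in geoms],
                "village_id": [p.get("village_id", i) for i, p in enumerate(props)],
            }
        )
    return scene, dem, points, overlays, villages


def build_classifier_spec(
    scene: MultiSeasonScene,
    dem: Raster,
    points: SurveyPoints,
    overlays: list,
    cfg: dict,
) -> tuple[ClassifierSpec, pd.DataFrame]:
    """Derive (or load) the decision tree and assemble the classifier spec."""
    m_threshold = float(cfg.get("m_threshold", 1.0))
    layers = dict(scene.layers)
    layers["dem"] = dem

    if cfg.get("tree_file"):
        with open(cfg["tree_file"]) as fh:
            tree = tree_from_dict(yaml.safe_load(fh))
        return ClassifierSpec(tree, overlays, m_threshold), pd.DataFrame()

    overlaid = {int(cls) for _, cls in overlays}
    order_labels = cfg.get("class_order")
    if order_labels:
        order = [int(PatchClass.from_label(s)) for s in order_labels]
    else:
        order = [c for c in DEFAULT_CLASS_ORDER if c not in overlaid]
    sigs = class_signatures(layers, points)
    sep = SeparabilityMatrix(sigs)
    tree = derive_tree(sigs, sep, order, m_threshold)
    return ClassifierSpec(tree, overlays, m_threshold), signatures_to_frame(sigs)


def build_score_table(cfg: dict) -> BenefitScoreTable:
    if not cfg.get("score_table"):
        return BenefitScoreTable()
    raw = cfg["score_table"]
    if isinstance(raw, str):
        raw = read_config(raw)
    scores = {
        (cls, Benefit(b)): float(v)
        for cls, per_b in raw["scores"].items()
        for b, v in per_b.items()
    }
    dw = {(c, Benefit(b)) for c, b in raw.get("distance_weighted", [])}
    aw = {(c, Benefit(b)) for c, b in raw.get("area_weighted", [])}
    return BenefitScoreTable(scores=scores, distance_weighted=dw, area_weighted=aw)


def build_benefit_maps(
    patch_map: Raster,
    villages: pd.DataFrame,
    cfg: dict,
) -> tuple[dict[Benefit, Raster], Raster, WeightRaster, WeightRaster]:
    table = build_score_table(cfg)
    grid = patch_map.grid
    homestead_mask = Raster(
        np.asarray(patch_map.data) == int(PatchClass.HOMESTEAD), grid
    )
    dist_w = homestead_distance_weights(
        homestead_mask,
        n_zones=int(cfg.get("n_zones", 5)),
        w_near=float(cfg.get("w_near", 1.2)),
        w_far=float(cfg.get("w_far", 0.8)),
        zone_width_m=float(cfg.get("zone_width_m", 500.0)),
    )
    territories = voronoi_territories(villages, grid)
    area_w = shrubland_area_weights(
        patch_map,
        territories,
        breakpoints=tuple(cfg.get("shrub_breakpoints", DEFAULT_SHRUB_BREAKPOINTS)),
        weights=tuple(cfg.get("shrub_weights", DEFAULT_SHRUB_WEIGHTS)),
    )
    maps = compute_all_benefit_maps(patch_map, table, dist_w, area_w)
    return maps, heat_map(maps), dist_w, area_w


# -- orchestration -----------------------------------------------------------


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", stage, dt)
                return False
            log.error("stage %s: FAILED after %.2fs: %s", stage, dt, exc)
            if not isinstance(exc, PipelineStageError):
                raise PipelineStageError(stage, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full pipeline for one config; optionally write artifacts."""
    out = Path(config.output_dir)
    truth = None

    with _timed("inputs"):
        if config.synthetic is not None:
            truth, scene, dem, points = build_synthetic_inputs(
                config.synthetic, config.seed
            )
            villages = truth.village_points
            overlays = [
                (truth.depression_polygons, PatchClass.DEPRESSION),
                (truth.homestead_polygons, PatchClass.HOMESTEAD),
                (truth.urban_polygons, PatchClass.URBAN),
            ]
            if config.synthetic.get("overlays") == "detect":
                det = detect_built_patches(
                    scene["brightness_dry"]
                    if "brightness_dry" in scene
                    else scene["red_dry"],
                    size_limits=(2, 200),
                    village_points=villages,
                )
                overlays = [
                    (truth.depression_polygons, PatchClass.DEPRESSION),
                    (det["homestead"], PatchClass.HOMESTEAD),
                    (det["urban"], PatchClass.URBAN),
                ]
            elif config.synthetic.get("overlays") == "none":
                overlays = []
        else:
            scene, dem, points, overlays, villages = load_real_inputs(config.real)
            if villages is None:
                raise ValueError("real-input config requires a 'villages' point file")

    with _timed("spectral_indices"):
        add_derived_layers(scene)

    with _timed("hybrid_classifier"):
        spec, sig_frame = build_classifier_spec(
            scene, dem, points, overlays, config.classifier
        )
        layers = dict(scene.layers)
        patch_map = classify(layers, spec, dem=dem)

    with _timed("benefit_mapping"):
        maps, heat, dist_w, area_w = build_benefit_maps(
            patch_map, villages, config.benefits
        )

    with _timed("accuracy_assessment"):
        buffer_m = float(config.accuracy.get("buffer_m", 15.0))
        report = assess(patch_map, points.groundtruth, buffer_m=buffer_m)

    if write:
        with _timed("write_artifacts"):
            out.mkdir(parents=True, exist_ok=True)
            write_raster(out / "patch_map.tif", patch_map)
            write_raster(out / "dem.tif", dem)
            for b, r in maps.items():
                write_raster(out / f"benefit_{b.value}.tif", r)
            write_raster(out / "heat_map.tif", heat)
            write_raster(out / "weights_distance.tif", dist_w.raster)
            write_raster(out / "weights_shrubland_area.tif", area_w.raster)
            write_json_report(out / "accuracy_report.json", report.to_dict())
            write_table(out / "composition_table.csv", report.composition_table())
            if len(sig_frame):
                write_table(out / "signatures.csv", sig_frame)
            (out / "tree.yaml").write_text(
                yaml.safe_dump(tree_to_dict(spec.tree), sort_keys=False)
            )
            (out / "legend.json").write_text(json.dumps(LEGEND, indent=2))
            write_survey_points(
                out / "survey_points.geojson", points, crs=patch_map.grid.crs
            )
            from shapely.geometry import Point

            write_vector(
                out / "villages.geojson",
                [Point(r["x"], r["y"]) for _, r in villages.iterrows()],
                [{"village_id": int(r["village_id"])} for _, r in villages.iterrows()],
                crs=patch_map.grid.crs,
            )
            provenance = {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "versions": {
                    "sepmap": __version__,
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                },
            }
            write_json_report(out / "provenance.json", provenance)

    return PipelineResult(
        patch_map=patch_map,
        benefit_maps=maps,
        heat=heat,
        report=report,
        truth=truth,
        output_dir=out,
    )
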