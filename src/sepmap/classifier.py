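"""Hybrid decision-tree classification of social-ecological patches.

The hybrid scheme combines preparatory steps — burning digitized vector
overlays (depressions, homesteads, urban land) into the map, or a simplified
object-based detector for built-up patches where no overlays exist — with a
binary decision tree over the spectral/index/elevation layers. Every node
splits the data in two on a single layer threshold; the end of every branch
is one class.

The tree itself is data-driven: ``derive_tree`` peels classes off one at a
time in a configurable order, choosing for each class the layer on which it
is most separable (worst-case M statistic against the remaining pool) and
thresholding at the midpoint between the class mean and the nearest
remaining-class mean. Trees are plain data and serialize to a small
human-editable mapping (see ``tree_to_dict``/``tree_from_dict``).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Union

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

from sepmap.classes import NODATA_CODE, PatchClass
from sepmap.grid import GridGeometry, Raster, check_aligned
from sepmap.indices import ClassSignature, SeparabilityMatrix

OPERATORS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}

Leaf = int  # terminal PatchClass code (or NODATA_CODE)
Branch = Union["DecisionNode", Leaf]


class CalibrationError(ValueError):
    """Raised when no layer separates a class pair at the required M."""


@dataclass
class DecisionNode:
    """One binary split: ``layer <op> threshold`` routes to the true branch."""

    layer: str
    operator: str
    threshold: float
    true_branch: Branch
    false_branch: Branch

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")

    def referenced_layers(self) -> set[str]:
        layers = {self.layer}
        for br in (self.true_branch, self.false_branch):
            if isinstance(br, DecisionNode):
                layers |= br.referenced_layers()
        return layers

    def leaves(self) -> set[int]:
        out: set[int] = set()
        for br in (self.true_branch, self.false_branch):
            if isinstance(br, DecisionNode):
                out |= br.leaves()
            else:
                out.add(int(br))
        return out

    def evaluate_pixel(self, values: dict[str, float]) -> int:
        """Route a single pixel's layer values through the tree."""
        node: Branch = self
        while isinstance(node, DecisionNode):
            cond = OPERATORS[node.operator](values[node.layer], node.threshold)
            node = node.true_branch if cond else node.false_branch
        return int(node)


@dataclass
class ClassifierSpec:
    """Preparatory overlays (applied in order, later wins) plus the tree."""

    tree: DecisionNode
    overlay_layers: list[tuple[object, PatchClass]] = dc_field(default_factory=list)
    m_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.m_threshold <= 0:
            raise ValueError("m_threshold must be > 0")


def _as_geometry(overlay) -> Polygon | MultiPolygon:
    if isinstance(overlay, (Polygon, MultiPolygon)):
        return overlay
    return unary_union(list(overlay))


def burn_overlays(
    grid: GridGeometry,
    overlays: list[tuple[object, PatchClass]],
) -> Raster:
    """Rasterize vector overlays: pixel centers strictly inside a polygon get
    that overlay's class; later overlays override earlier ones; all other
    pixels stay unassigned (code 0)."""
    out = np.zeros(grid.shape, dtype=np.int16)
    if not overlays:
        return Raster(out, grid, nodata=NODATA_CODE)
    X, Y = grid.center_meshgrid()
    for overlay, cls in overlays:
        geom = _as_geometry(overlay)
        if geom.is_empty:
            continue
        # limit the point-in-polygon test to the geometry's bounding box
        gxmin, gymin, gxmax, gymax = geom.bounds
        sub = (X >= gxmin) & (X <= gxmax) & (Y >= gymin) & (Y <= gymax)
        if not sub.any():
            continue
        rows, cols = np.nonzero(sub)
        hit = contains_xy(geom, X[rows, cols], Y[rows, cols])
        out[rows[hit], cols[hit]] = int(cls)
    return Raster(out, grid, nodata=NODATA_CODE)


def detect_built_patches(
    brightness: Raster,
    size_limits: tuple[int, int],
    village_points: pd.DataFrame | None = None,
    threshold: float | None = None,
    village_radius_m: float = 500.0,
) -> dict[str, list[Polygon]]:
    """Simplified object-based detection of built-up patches.

    Thresholds high-brightness pixels (strictly ``>``), extracts
    8-connected components, and sorts them by size: components within
    ``[min_px, max_px]`` become homestead candidates; larger components that
    overlap a village point's neighborhood become urban candidates; the rest
    are dropped. Default threshold is the 95th percentile of valid
    brightness.
    """
    min_px, max_px = size_limits
    data = np.asarray(brightness.data, dtype=float)
    valid = brightness.mask & ~np.isnan(data)
    if threshold is None:
        threshold = float(np.percentile(data[valid], 95)) if valid.any() else np.inf
    bright = valid & (data > threshold)
    labeled, n = ndimage.label(bright, structure=np.ones((3, 3), dtype=int))
    grid = brightness.grid

    village_rc: list[tuple[int, int]] = []
    if village_points is not None and len(village_points):
        vx = np.asarray(village_points["x"], float)
        vy = np.asarray(village_points["y"], float)
        inside = grid.contains(vx, vy)
        r, c = grid.xy_to_rowcol(vx[inside], vy[inside])
        village_rc = list(zip(r.tolist(), c.tolist()))
    radius_px = village_radius_m / grid.pixel_size

    out: dict[str, list[Polygon]] = {"homestead": [], "urban": []}
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labeled == comp)
        size = len(rows)
        if size < min_px:
            continue
        near_village = any(
            np.min(np.hypot(rows - vr, cols - vc)) <= radius_px
            for vr, vc in village_rc
        )
        if size > max_px:
            if not near_village:
                continue
            bucket = "urban"
        else:
            bucket = "homestead"
        cells = [box(*grid.cell_bounds(int(r), int(c))) for r, c in zip(rows, cols)]
        merged = unary_union(cells)
        geoms = merged.geoms if isinstance(merged, MultiPolygon) else [merged]
        out[bucket].extend(geoms)
    return out


def derive_tree(
    signatures: list[ClassSignature],
    separability: SeparabilityMatrix,
    class_order: list[int],
    m_threshold: float = 1.0,
) -> DecisionNode:
    """Assemble a peeling tree from calibration statistics.

    For each class in order, pick the layer maximizing the worst-case M
    against the pool of still-unassigned classes, among layers on which the
    class mean is extremal (a single threshold can only peel off one end of
    the pool); split at the midpoint
    between the class mean and the nearest remaining-class mean on that
    layer (ties route to the true branch via <=/>=). The last class becomes
    the default leaf. Raises :class:`CalibrationError`, naming the offending
    class pair, if no layer reaches ``m_threshold`` for some split.
    """
    if len(class_order) < 2:
        raise ValueError("class_order needs at least two classes")
    by_code = {s.class_code for s in signatures}
    missing = set(class_order) - by_code
    if missing:
        raise ValueError(
            f"signatures missing for classes: {sorted(PatchClass(c).label for c in missing)}"
        )

    nodes: list[tuple[str, str, float, int]] = []  # (layer, op, threshold, class)
    remaining = list(class_order)
    while len(remaining) > 1:
        c = remaining[0]
        others = remaining[1:]
        best: tuple[float, str, int] | None = None  # (worst_m, layer, argmin_other)
        for layer_name in separability.layers:
            if not all(separability.has(layer_name, k) for k in remaining):
                continue
            # a single threshold can only peel a class whose mean is extremal
            # on the layer: every remaining mean must lie on one side
            mean_c = separability.signature(layer_name, c).mean
            deltas = [
                separability.signature(layer_name, o).mean - mean_c for o in others
            ]
            if not (all(d > 0 for d in deltas) or all(d < 0 for d in deltas)):
                continue
            ms = [(separability.m(layer_name, c, o), o) for o in others]
            worst_m, worst_o = min(ms, key=lambda t: t[0])
            if best is None or worst_m > best[0]:
                best = (worst_m, layer_name, worst_o)
        if best is None:
            raise CalibrationError(
                f"no layer places {PatchClass(c).label!r} on one side of the "
                f"remaining classes {[PatchClass(k).label for k in others]}"
            )
        worst_m, layer_name, worst_other = best
        if worst_m < m_threshold:
            raise CalibrationError(
                f"classes {PatchClass(c).label!r} and "
                f"{PatchClass(worst_other).label!r} are not separable at "
                f"M >= {m_threshold} (best layer {layer_name!r}, M = {worst_m:.3f})"
            )
        mean_c = separability.signature(layer_name, c).mean
        nearest = min(
            others, key=lambda o: abs(separability.signature(layer_name, o).mean - mean_c)
        )
        mean_near = separability.signature(layer_name, nearest).mean
        thr = 0.5 * (mean_c + mean_near)
        op = "<=" if mean_c <= mean_near else ">="
        nodes.append((layer_name, op, thr, c))
        remaining = others

    tree: Branch = remaining[0]  # default leaf
    for layer_name, op, thr, c in reversed(nodes):
        tree = DecisionNode(
            layer=layer_name,
            operator=op,
            threshold=float(thr),
            true_branch=int(c),
            false_branch=tree,
        )
    assert isinstance(tree, DecisionNode)
    return tree


def _evaluate_tree(
    tree: Branch,
    layer_data: dict[str, np.ndarray],
    mask: np.ndarray,
    out: np.ndarray,
) -> None:
    if not isinstance(tree, DecisionNode):
        out[mask] = int(tree)
        return
    cond = OPERATORS[tree.operator](layer_data[tree.layer], tree.threshold)
    _evaluate_tree(tree.true_branch, layer_data, mask & cond, out)
    _evaluate_tree(tree.false_branch, layer_data, mask & ~cond, out)


def classify(
    scene_layers: dict[str, Raster],
    spec: ClassifierSpec,
    dem: Raster | None = None,
) -> Raster:
    """Produce the patch map: overlays first, then the tree everywhere else.

    Overlay-assigned pixels are never overwritten by tree evaluation.
    Remaining pixels that are valid in every layer the tree references are
    routed to exactly one class; pixels that are nodata in any referenced
    layer stay nodata. Raises before any pixel is processed if the tree
    references a missing layer.
    """
    layers = dict(scene_layers)
    if dem is not None:
        layers.setdefault("dem", dem)
    referenced = spec.tree.referenced_layers()
    missing = referenced - set(layers)
    if missing:
        raise ValueError(f"tree references missing layer(s): {sorted(missing)}")
    grid = check_aligned(*(layers[name] for name in sorted(referenced)))

    burned = burn_overlays(grid, spec.overlay_layers)
    out = burned.data.astype(np.int16).copy()

    valid = np.ones(grid.shape, dtype=bool)
    for name in referenced:
        valid &= layers[name].mask
    todo = (out == NODATA_CODE) & valid
    layer_data = {
        name: np.asarray(layers[name].data, dtype=float) for name in referenced
    }
    _evaluate_tree(spec.tree, layer_data, todo, out)

    from sepmap.classes import LEGEND

    return Raster(out, grid, nodata=NODATA_CODE, legend=dict(LEGEND))


# -- tree serialization ------------------------------------------------------


def tree_to_dict(node: Branch) -> object:
    """Serializable form: leaves are class labels, nodes small mappings."""
    if not isinstance(node, DecisionNode):
        code = int(node)
        return "nodata" if code == NODATA_CODE else PatchClass(code).label
    return {
        "layer": node.layer,
        "operator": node.operator,
        "threshold": float(node.threshold),
        "true": tree_to_dict(node.true_branch),
        "false": tree_to_dict(node.false_branch),
    }


def tree_from_dict(obj: object) -> Branch:
    if isinstance(obj, str):
        return NODATA_CODE if obj == "nodata" else int(PatchClass.from_label(obj))
    if not isinstance(obj, dict):
        raise ValueError(f"invalid tree node: {obj!r}")
    return DecisionNode(
        layer=obj["layer"],
        operator=obj["operator"],
        threshold=float(obj["threshold"]),
        true_branch=tree_from_dict(obj["true"]),
        false_branch=tree_from_dict(obj["false"]),
    )


#: default class peeling order: biomass-defined classes first, bare soil last
DEFAULT_CLASS_ORDER = [
    int(PatchClass.WATER),
    int(PatchClass.FOREST),
    int(PatchClass.DEPRESSION),
    int(PatchClass.SHRUBLAND),
    int(PatchClass.FIELD),
    int(PatchClass.BARE_SOIL),
]
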