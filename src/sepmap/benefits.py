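"""Livelihood-benefit rasters from a social-ecological patch map.

Each patch class scores a per-unit-area contribution to five livelihood
benefits (annual crops for consumption; nutritional diversity & medicinal
uses; material assets & energy; saving/insurance; income). Two weight
mechanisms modulate the scores, both bounded in [0.8, 1.2]:

* distance decay — for fields and shrubland, every benefit except
  saving/insurance loses value with walking distance from the nearest
  homestead (five buffer zones, nearest 1.2 down to 0.8);
* shrubland area — within each village territory (Thiessen/Voronoi polygon
  around the village point), the value of shrubland-derived benefits is a
  hump-shaped function of how much shrubland the village has: too little
  cannot sustain use, too much is inaccessible surplus.

The composite "heat map" is the plain per-pixel sum of the five benefit
maps. Water and urban land are land covers, not patches, and score zero
everywhere.

The shipped numeric score table encodes the qualitative field findings as
integers on a 0-5 scale and is a mandatory, swappable configuration input —
users with their own focus-group scores substitute them wholesale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from enum import Enum

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, MultiPolygon, Polygon

from sepmap.classes import LAND_COVER_CLASSES, PatchClass
from sepmap.grid import GridGeometry, Raster, check_aligned


class Benefit(str, Enum):
    """The five livelihood benefits."""

    ANNUAL_CROPS = "annual_crops"
    NUTRITIONAL_DIVERSITY_MEDICINAL = "nutritional_diversity_medicinal"
    MATERIAL_ASSETS_ENERGY = "material_assets_energy"
    SAVING_INSURANCE = "saving_insurance"
    INCOME = "income"


BENEFITS = tuple(Benefit)

# columns: annual_crops, nutritional_diversity_medicinal,
#          material_assets_energy, saving_insurance, income
_DEFAULT_SCORES: dict[str, tuple[float, float, float, float, float]] = {
    "bare_soil": (0, 1, 1, 1, 0),
    "depression": (4, 4, 2, 3, 4),
    "field": (5, 3, 2, 3, 3),
    "forest": (0, 4, 3, 2, 2),
    "homestead": (3, 4, 3, 3, 2),
    "shrubland": (0, 3, 4, 3, 2),
    "water": (0, 0, 0, 0, 0),
    "urban": (0, 0, 0, 0, 0),
}

_DISTANCE_WEIGHTED_DEFAULT = {
    (cls, b)
    for cls in ("field", "shrubland")
    for b in Benefit
    if b is not Benefit.SAVING_INSURANCE
}

_AREA_WEIGHTED_DEFAULT = {
    ("shrubland", b)
    for b in (
        Benefit.NUTRITIONAL_DIVERSITY_MEDICINAL,
        Benefit.MATERIAL_ASSETS_ENERGY,
        Benefit.SAVING_INSURANCE,
    )
}


@dataclass
class BenefitScoreTable:
    """Per-patch, per-benefit scores plus weighting applicability flags."""

    scores: dict[tuple[str, Benefit], float] = dc_field(
        default_factory=lambda: {
            (cls, b): float(v)
            for cls, row in _DEFAULT_SCORES.items()
            for b, v in zip(Benefit, row)
        }
    )
    distance_weighted: set[tuple[str, Benefit]] = dc_field(
        default_factory=lambda: set(_DISTANCE_WEIGHTED_DEFAULT)
    )
    area_weighted: set[tuple[str, Benefit]] = dc_field(
        default_factory=lambda: set(_AREA_WEIGHTED_DEFAULT)
    )

    def __post_init__(self) -> None:
        for (cls, b), v in self.scores.items():
            PatchClass.from_label(cls)
            if v < 0:
                raise ValueError(f"negative score for ({cls}, {b.value}): {v}")
            if PatchClass.from_label(cls) in LAND_COVER_CLASSES and v != 0:
                raise ValueError(f"land cover {cls!r} must score 0, got {v}")

    def score(self, class_code: int, benefit: Benefit) -> float:
        key = (PatchClass(class_code).label, benefit)
        if key not in self.scores:
            raise KeyError(
                f"no score entry for class {key[0]!r}, benefit {benefit.value!r}"
            )
        return self.scores[key]

    def is_distance_weighted(self, class_code: int, benefit: Benefit) -> bool:
        return (PatchClass(class_code).label, benefit) in self.distance_weighted

    def is_area_weighted(self, class_code: int, benefit: Benefit) -> bool:
        return (PatchClass(class_code).label, benefit) in self.area_weighted


@dataclass
class WeightRaster:
    """Multiplicative weight surface; every defined value in [0.8, 1.2]."""

    raster: Raster
    kind: str  # "distance" | "shrubland_area"

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "shrubland_area"):
            raise ValueError(f"unknown weight-raster kind {self.kind!r}")
        vals = np.asarray(self.raster.data, float)[self.raster.mask]
        if vals.size and (vals.min() < 0.8 - 1e-12 or vals.max() > 1.2 + 1e-12):
            raise ValueError(
                f"weight values outside [0.8, 1.2]: [{vals.min()}, {vals.max()}]"
            )


@dataclass
class VillageTerritories:
    """Voronoi (Thiessen) polygons per village, clipped to the study extent."""

    polygons: dict[int, Polygon | MultiPolygon]
    grid: GridGeometry
    shrubland_fraction: dict[int, float] = dc_field(default_factory=dict)

    @property
    def total_area(self) -> float:
        return sum(p.area for p in self.polygons.values())


def voronoi_territories(
    village_points: pd.DataFrame, extent: GridGeometry
) -> VillageTerritories:
    """Thiessen polygons from village points, clipped to the grid extent.

    Rejects duplicate points. Total clipped polygon area equals the extent
    area (the cells partition it).
    """
    xs = village_points["x"].to_numpy(float)
    ys = village_points["y"].to_numpy(float)
    ids = village_points["village_id"].to_numpy(int)
    if len(xs) == 0:
        raise ValueError("need at least one village point")
    coords = np.column_stack([xs, ys])
    if len(np.unique(coords, axis=0)) != len(coords):
        raise ValueError("duplicate village points")

    frame = extent.extent_polygon
    if len(xs) == 1:
        return VillageTerritories({int(ids[0]): frame}, extent)

    cells = shapely.voronoi_polygons(
        MultiPoint(coords.tolist()), extend_to=frame.buffer(extent.pixel_size)
    )
    polygons: dict[int, Polygon | MultiPolygon] = {}
    for cell in cells.geoms:
        clipped = cell.intersection(frame)
        if clipped.is_empty:
            continue
        inside = [
            i for i in range(len(xs)) if cell.covers(shapely.points(xs[i], ys[i]))
        ]
        if len(inside) != 1:
            # boundary-degenerate cell; resolve by nearest seed to centroid
            cx, cy = clipped.centroid.x, clipped.centroid.y
            inside = [int(np.argmin(np.hypot(xs - cx, ys - cy)))]
        polygons[int(ids[inside[0]])] = clipped
    if len(polygons) != len(xs):
        raise ValueError("Voronoi cell assignment failed to cover every village")
    return VillageTerritories(polygons, extent)


def homestead_distance_weights(
    homestead_mask: Raster,
    n_zones: int = 5,
    w_near: float = 1.2,
    w_far: float = 0.8,
    zone_width_m: float = 500.0,
) -> WeightRaster:
    """Distance-decay weights in five annular buffer zones around homesteads.

    Zone 0 (containing the homesteads themselves) gets ``w_near``; weights
    interpolate linearly down to ``w_far`` in the outermost zone, and any
    pixel beyond the last zone keeps ``w_far``.
    """
    if zone_width_m <= 0:
        raise ValueError("zone_width_m must be > 0")
    if n_zones < 2:
        raise ValueError("need at least two zones")
    grid = homestead_mask.grid
    grid.require_metric()
    mask = np.asarray(homestead_mask.data).astype(bool)
    if not mask.any():
        raise ValueError("homestead mask is empty: no anchor for distances")
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.pixel_size)
    zone = np.minimum((dist // zone_width_m).astype(int), n_zones - 1)
    steps = np.linspace(w_near, w_far, n_zones)
    return WeightRaster(Raster(steps[zone], grid, nodata=None), kind="distance")


DEFAULT_SHRUB_BREAKPOINTS = (0.02, 0.10, 0.25, 0.40)
DEFAULT_SHRUB_WEIGHTS = (0.8, 1.0, 1.2, 1.1, 0.9)


def shrubland_area_weights(
    patch_map: Raster,
    territories: VillageTerritories,
    breakpoints: tuple[float, ...] = DEFAULT_SHRUB_BREAKPOINTS,
    weights: tuple[float, ...] = DEFAULT_SHRUB_WEIGHTS,
) -> WeightRaster:
    """Per-village weights from each territory's shrubland fraction.

    The shrubland fraction of every territory's pixels is binned by the
    four breakpoints into five categories with a hump-shaped default weight
    schedule; every pixel of the territory receives its category weight.
    Pixels are assigned to territories by nearest village point, which
    coincides with the Voronoi partition.
    """
    if len(breakpoints) + 1 != len(weights):
        raise ValueError("need one more weight than breakpoints")
    if any(b2 <= b1 for b1, b2 in zip(breakpoints, breakpoints[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if any(not 0.8 <= w <= 1.2 for w in weights):
        raise ValueError("weights must lie in [0.8, 1.2]")
    if patch_map.grid != territories.grid:
        raise ValueError("patch map and territories are on different grids")
    grid = patch_map.grid
    grid.require_metric()

    # assign pixel centers to territories by polygon membership; cells are
    # interior-disjoint so each center lands in exactly one (boundary centers
    # go to the lowest village id, a measure-zero tie-break)
    vids = sorted(territories.polygons)
    X, Y = grid.center_meshgrid()
    assignment = np.full(grid.shape, -1, dtype=int)
    for vid in vids:
        poly = territories.polygons[vid]
        unassigned = assignment < 0
        if not unassigned.any():
            break
        rows, cols = np.nonzero(unassigned)
        hit = shapely.covers(poly, shapely.points(X[rows, cols], Y[rows, cols]))
        assignment[rows[hit], cols[hit]] = vid

    shrub = np.asarray(patch_map.data) == int(PatchClass.SHRUBLAND)
    valid = patch_map.mask
    out = np.ones(grid.shape, dtype=float)
    fractions: dict[int, float] = {}
    for vid in vids:
        sel = (assignment == vid) & valid
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"territory {vid} contains no pixels; weight 1.0", stacklevel=2)
            fractions[vid] = float("nan")
            continue
        frac = float(shrub[sel].sum()) / n
        fractions[vid] = frac
        cat = int(np.searchsorted(np.asarray(breakpoints), frac, side="right"))
        out[assignment == vid] = weights[cat]
    territories.shrubland_fraction = fractions
    return WeightRaster(Raster(out, grid, nodata=None), kind="shrubland_area")


def compute_benefit_map(
    patch_map: Raster,
    table: BenefitScoreTable,
    dist_w: WeightRaster,
    area_w: WeightRaster,
    benefit: Benefit,
) -> Raster:
    """One benefit raster: score(class, benefit) x applicable weights.

    The distance and area weights each apply only where the score table
    flags the (class, benefit) pair; where both apply they compose
    multiplicatively. Water/urban pixels are 0 (their scores are 0);
    nodata pixels propagate as NaN.
    """
    grid = check_aligned(patch_map, dist_w.raster, area_w.raster)
    codes = np.asarray(patch_map.data).astype(int)
    present = np.unique(codes[patch_map.mask])

    max_code = int(max(PatchClass))
    score_lut = np.zeros(max_code + 1)
    dflag_lut = np.zeros(max_code + 1, dtype=bool)
    aflag_lut = np.zeros(max_code + 1, dtype=bool)
    for c in present:
        score_lut[c] = table.score(int(c), benefit)  # KeyError if entry missing
        dflag_lut[c] = table.is_distance_weighted(int(c), benefit)
        aflag_lut[c] = table.is_area_weighted(int(c), benefit)

    safe = np.where(patch_map.mask, codes, 0)
    value = score_lut[safe]
    dw = np.where(dflag_lut[safe], np.asarray(dist_w.raster.data, float), 1.0)
    aw = np.where(aflag_lut[safe], np.asarray(area_w.raster.data, float), 1.0)
    out = value * dw * aw
    out[~patch_map.mask] = np.nan
    return Raster(out, grid, nodata=np.nan)


def compute_all_benefit_maps(
    patch_map: Raster,
    table: BenefitScoreTable,
    dist_w: WeightRaster,
    area_w: WeightRaster,
) -> dict[Benefit, Raster]:
    return {
        b: compute_benefit_map(patch_map, table, dist_w, area_w, b) for b in BENEFITS
    }


def heat_map(benefit_maps: list[Raster] | dict[Benefit, Raster]) -> Raster:
    """Composite multifunctionality map: per-pixel sum of the five benefit
    maps; NaN wherever any input is nodata."""
    maps = list(benefit_maps.values()) if isinstance(benefit_maps, dict) else list(benefit_maps)
    if len(maps) != len(BENEFITS):
        raise ValueError(f"expected {len(BENEFITS)} benefit maps, got {len(maps)}")
    grid = check_aligned(*maps)
    acc = np.zeros(grid.shape, dtype=float)
    valid = np.ones(grid.shape, dtype=bool)
    for r in maps:
        acc += np.where(r.mask, np.asarray(r.data, float), 0.0)
        valid &= r.mask
    acc[~valid] = np.nan
    return Raster(acc, grid, nodata=np.nan)
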