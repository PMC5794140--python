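"""Synthetic study-area generator with known patch ground truth.

Produces everything the real pipeline consumes — a social-ecological patch
mosaic, two-season spectral imagery drawn from per-class Gaussian signatures,
a digital elevation model with carved depressions, village points, vector
overlays (homesteads, depressions, urban land) that rasterize exactly back to
the patch map, and transect survey points — so classification, benefit
mapping and accuracy assessment can be tested against a known truth.

The mosaic emulates the patchy, village-centred structure of semi-arid
smallholder landscapes: homesteads cluster around village points, urban land
forms one contiguous block around a designated town, and the remaining
classes grow as compact blobs from random nuclei until target area fractions
are met (remainder: bare soil). Default area fractions follow the published
composition of a northern-Burkina-Faso province-scale study area (fields
~50%, shrubland ~29%, bare soil ~11%, depressions 6%, small shares of
forest, homesteads, water and urban land).

Spectral signatures are free parameters of the generator (per class x season
x band mean/std reflectance); the defaults are chosen to reproduce the
qualitative seasonal behaviour that the classifier exploits — green
vegetation dark in red and bright in NIR during the rains, bare and built
surfaces bright in all bands, water dark everywhere — not calibrated to any
particular sensor's radiometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

from sepmap.classes import NODATA_CODE, PatchClass
from sepmap.grid import GridGeometry, Raster
from sepmap.points import SurveyPoints
from sepmap.scene import BANDS, SEASONS, MultiSeasonScene

# -- default generator condition tables -------------------------------------

#: mean reflectance per class, season, band (red, nir, mir), in [0, 1]
DEFAULT_SIGNATURE_MEANS: dict[str, dict[str, tuple[float, float, float]]] = {
    "bare_soil": {"dry": (0.30, 0.38, 0.45), "rainy": (0.28, 0.36, 0.42)},
    "depression": {"dry": (0.12, 0.30, 0.18), "rainy": (0.07, 0.45, 0.12)},
    "field": {"dry": (0.25, 0.33, 0.38), "rainy": (0.08, 0.48, 0.20)},
    "forest": {"dry": (0.06, 0.35, 0.15), "rainy": (0.05, 0.50, 0.12)},
    "homestead": {"dry": (0.34, 0.40, 0.50), "rainy": (0.30, 0.38, 0.46)},
    "shrubland": {"dry": (0.18, 0.30, 0.30), "rainy": (0.12, 0.40, 0.22)},
    "water": {"dry": (0.05, 0.03, 0.02), "rainy": (0.06, 0.03, 0.02)},
    "urban": {"dry": (0.38, 0.42, 0.55), "rainy": (0.36, 0.40, 0.52)},
}

#: per-band reflectance noise standard deviation shared by all classes
DEFAULT_SIGNATURE_STD = 0.01

#: default patch-mosaic composition (fractions of the landscape; the
#: remainder is bare soil)
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "field": 0.50,
    "shrubland": 0.29,
    "depression": 0.06,
    "forest": 0.005,
    "homestead": 0.028,
    "water": 0.002,
    "urban": 0.005,
}


@dataclass
class SpectralSignatureModel:
    """Per class x season x band Gaussian reflectance model plus DEM parameters.

    ``means[label][season]`` is a (red, nir, mir) tuple in [0, 1];
    ``stds`` either a scalar applied everywhere or a nested dict of the same
    shape. DEM parameters are in meters.
    """

    means: dict[str, dict[str, tuple[float, float, float]]] = dc_field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_SIGNATURE_MEANS.items()
        }
    )
    stds: float | dict[str, dict[str, tuple[float, float, float]]] = (
        DEFAULT_SIGNATURE_STD
    )
    dem_base_m: float = 300.0
    dem_relief_m: float = 6.0
    dem_depression_lowering_m: float = 8.0
    dem_smoothing_px: float = 8.0

    def __post_init__(self) -> None:
        for label, per_season in self.means.items():
            PatchClass.from_label(label)
            for season, mu in per_season.items():
                if season not in SEASONS:
                    raise ValueError(f"unknown season {season!r}")
                if any(not (0.0 <= m <= 1.0) for m in mu):
                    raise ValueError(
                        f"reflectance means must lie in [0, 1]: {label}/{season}={mu}"
                    )
        if isinstance(self.stds, (int, float)):
            if self.stds < 0:
                raise ValueError("signature std must be >= 0")
        else:
            for per_season in self.stds.values():
                for sd in per_season.values():
                    if any(s < 0 for s in sd):
                        raise ValueError("signature std must be >= 0")

    def mean(self, label: str, season: str, band: str) -> float:
        return self.means[label][season][BANDS.index(band)]

    def std(self, label: str, season: str, band: str) -> float:
        if isinstance(self.stds, (int, float)):
            return float(self.stds)
        return self.stds[label][season][BANDS.index(band)]


@dataclass
class LayoutConfig:
    """Geometry and composition targets for the synthetic mosaic."""

    shape: tuple[int, int] = (300, 300)
    pixel_size: float = 30.0
    origin_x: float = 500_000.0
    origin_y: float = 1_500_000.0
    crs: str = "EPSG:32630"
    crs_units: str = "m"
    class_fractions: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    fraction_tolerance: float = 0.05
    n_villages: int = 6
    #: mean blob size (pixels) for region-grown classes
    patch_mean_px: int = 300
    #: homestead cluster radius is implied by per-village quota

    def __post_init__(self) -> None:
        for label, frac in self.class_fractions.items():
            PatchClass.from_label(label)
            if frac < 0:
                raise ValueError(f"negative class fraction for {label}: {frac}")
        if sum(self.class_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")

    def grid(self) -> GridGeometry:
        g = GridGeometry(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            pixel_size=self.pixel_size,
            shape=self.shape,
            crs=self.crs,
            crs_units=self.crs_units,
        )
        g.require_metric()
        return g


@dataclass
class LandscapeTruth:
    """Known ground truth: patch raster, villages and exact vector overlays."""

    patch_raster: Raster
    village_points: pd.DataFrame  # columns x, y, village_id
    homestead_polygons: list[Polygon]
    depression_polygons: list[Polygon]
    urban_polygons: list[Polygon]

    def __post_init__(self) -> None:
        inside = self.patch_raster.grid.contains(
            self.village_points["x"].to_numpy(), self.village_points["y"].to_numpy()
        )
        if not np.all(inside):
            raise ValueError("village point outside grid extent")


def _mask_to_polygons(mask: np.ndarray, grid: GridGeometry) -> list[Polygon]:
    """Union the cells of each connected component into polygons.

    The result rasterizes exactly back to ``mask`` under the pixel-center
    point-in-polygon rule used by overlay burning.
    """
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    polys: list[Polygon] = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labeled == comp)
        cells = [box(*grid.cell_bounds(int(r), int(c))) for r, c in zip(rows, cols)]
        merged = unary_union(cells)
        if isinstance(merged, MultiPolygon):
            polys.extend(merged.geoms)
        else:
            polys.append(merged)
    return polys


def _place_villages(
    grid: GridGeometry, n_villages: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Scatter villages with a minimum mutual separation (best effort)."""
    xmin, ymin, xmax, ymax = grid.extent
    margin = 0.1 * min(xmax - xmin, ymax - ymin)
    min_sep = 0.6 * np.sqrt((xmax - xmin) * (ymax - ymin) / max(n_villages, 1))
    xs, ys = [], []
    attempts = 0
    while len(xs) < n_villages and attempts < 2000:
        attempts += 1
        x = rng.uniform(xmin + margin, xmax - margin)
        y = rng.uniform(ymin + margin, ymax - margin)
        if all(np.hypot(x - xi, y - yi) >= min_sep for xi, yi in zip(xs, ys)):
            xs.append(x)
            ys.append(y)
    while len(xs) < n_villages:  # relax separation if the rejection loop stalls
        xs.append(rng.uniform(xmin + margin, xmax - margin))
        ys.append(rng.uniform(ymin + margin, ymax - margin))
    return pd.DataFrame(
        {"x": xs, "y": ys, "village_id": np.arange(n_villages, dtype=int)}
    )


def _claim_nearest(
    labels: np.ndarray,
    grid: GridGeometry,
    center_xy: tuple[float, float],
    n_px: int,
    code: int,
) -> None:
    """Assign the n_px unclaimed pixels nearest to a center point."""
    free = labels == 0
    if n_px <= 0 or not free.any():
        return
    cx, cy = center_xy
    X, Y = grid.center_meshgrid()
    d = np.hypot(X - cx, Y - cy)
    d[~free] = np.inf
    flat = np.argsort(d, axis=None, kind="stable")[: min(n_px, int(free.sum()))]
    rows, cols = np.unravel_index(flat, labels.shape)
    labels[rows, cols] = code


def _grow_class(
    labels: np.ndarray,
    code: int,
    quota_px: int,
    n_seeds: int,
    rng: np.random.Generator,
) -> None:
    """Seeded region growth: dilate blobs into unclaimed pixels up to a quota."""
    struct = np.ones((3, 3), dtype=bool)
    claimed = 0

    def seed_one() -> bool:
        free_rows, free_cols = np.nonzero(labels == 0)
        if len(free_rows) == 0:
            return False
        i = rng.integers(len(free_rows))
        labels[free_rows[i], free_cols[i]] = code
        return True

    for _ in range(max(1, n_seeds)):
        if claimed >= quota_px or not seed_one():
            break
        claimed += 1

    stall_guard = 0
    while claimed < quota_px:
        mask = labels == code
        ring = ndimage.binary_dilation(mask, structure=struct) & (labels == 0)
        n_ring = int(ring.sum())
        if n_ring == 0:
            if not seed_one():
                break  # grid exhausted
            claimed += 1
            stall_guard += 1
            if stall_guard > quota_px:
                break
            continue
        take = min(n_ring, quota_px - claimed)
        rows, cols = np.nonzero(ring)
        if take < n_ring:
            pick = rng.choice(n_ring, size=take, replace=False)
            rows, cols = rows[pick], cols[pick]
        labels[rows, cols] = code
        claimed += take


def generate_landscape(
    model: SpectralSignatureModel | None = None,
    layout: LayoutConfig | None = None,
    seed: int = 0,
) -> tuple[LandscapeTruth, MultiSeasonScene, Raster]:
    """Generate a synthetic landscape: truth, two-season scene, and DEM.

    Deterministic given ``seed``. Realized class fractions match the layout
    targets to within one blob's rounding (the growth claims exactly the
    pixel quota unless the grid fills up).

    Returns
    -------
    (LandscapeTruth, MultiSeasonScene, Raster)
        Ground truth with exact vector overlays, the spectral scene drawn
        from the signature model, and the elevation raster (meters).
    """
    model = model or SpectralSignatureModel()
    layout = layout or LayoutConfig()
    grid = layout.grid()
    rng = np.random.default_rng(seed)
    n_rows, n_cols = grid.shape
    n_px = n_rows * n_cols

    labels = np.zeros(grid.shape, dtype=np.int16)
    fractions = dict(layout.class_fractions)
    quotas = {lab: int(round(frac * n_px)) for lab, frac in fractions.items()}

    villages = _place_villages(grid, layout.n_villages, rng)

    # urban: one contiguous block around the designated town (village 0)
    if quotas.get("urban", 0) > 0:
        town = villages.iloc[0]
        _claim_nearest(
            labels, grid, (town["x"], town["y"]), quotas["urban"], int(PatchClass.URBAN)
        )

    # homesteads: compact clusters around every village point
    if quotas.get("homestead", 0) > 0:
        per_village = np.full(len(villages), quotas["homestead"] // len(villages))
        per_village[: quotas["homestead"] % len(villages)] += 1
        for (_, v), q in zip(villages.iterrows(), per_village):
            _claim_nearest(labels, grid, (v["x"], v["y"]), int(q), int(PatchClass.HOMESTEAD))

    # remaining classes grow as blobs from random nuclei
    for lab in ("water", "forest", "depression", "shrubland", "field"):
        q = quotas.get(lab, 0)
        if q > 0:
            n_seeds = max(1, q // layout.patch_mean_px)
            _grow_class(labels, int(PatchClass.from_label(lab)), q, n_seeds, rng)

    labels[labels == 0] = int(PatchClass.BARE_SOIL)

    patch_raster = Raster(labels, grid, nodata=NODATA_CODE)

    homestead_polys = _mask_to_polygons(labels == int(PatchClass.HOMESTEAD), grid)
    depression_polys = _mask_to_polygons(labels == int(PatchClass.DEPRESSION), grid)
    urban_polys = _mask_to_polygons(labels == int(PatchClass.URBAN), grid)

    truth = LandscapeTruth(
        patch_raster=patch_raster,
        village_points=villages,
        homestead_polygons=homestead_polys,
        depression_polygons=depression_polys,
        urban_polygons=urban_polys,
    )

    # DEM: smooth random relief with depressions carved below their surroundings
    base_noise = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(base_noise, sigma=model.dem_smoothing_px)
    if smooth.std() > 0:
        smooth = smooth / smooth.std()
    dem = model.dem_base_m + model.dem_relief_m * smooth
    depression_mask = (labels == int(PatchClass.DEPRESSION)).astype(float)
    carve = ndimage.gaussian_filter(depression_mask, sigma=1.0)
    if carve.max() > 0:
        carve = carve / carve.max()
    dem = dem - model.dem_depression_lowering_m * carve
    dem_raster = Raster(dem.astype(np.float64), grid, nodata=np.nan)

    # spectral scene: per-pixel Gaussian draw around the class signature
    arrays: dict[tuple[str, str], np.ndarray] = {}
    for season in SEASONS:
        for band in BANDS:
            mean_lut = np.zeros(int(max(PatchClass)) + 1)
            std_lut = np.zeros(int(max(PatchClass)) + 1)
            for c in PatchClass:
                mean_lut[int(c)] = model.mean(c.label, season, band)
                std_lut[int(c)] = model.std(c.label, season, band)
            mu = mean_lut[labels]
            sd = std_lut[labels]
            arr = mu + sd * rng.standard_normal(grid.shape)
            arrays[(season, band)] = np.clip(arr, 0.0, 1.0)
    scene = MultiSeasonScene.from_band_arrays(grid, arrays, nodata=np.nan)

    return truth, scene, dem_raster


def sample_calibration_pixels(
    truth: LandscapeTruth,
    n_per_class: int = 30,
    seed: int = 0,
) -> SurveyPoints:
    """Stratified calibration sample at known pixel centers.

    Emulates calibration data digitized from pre-existing village maps:
    up to ``n_per_class`` pixels per present class, located exactly at
    pixel centers (no GPS error), all with role ``"calibration"``.
    """
    rng = np.random.default_rng(seed)
    grid = truth.patch_raster.grid
    labels = truth.patch_raster.data
    xs, ys, cls = [], [], []
    for c in np.unique(labels[labels != NODATA_CODE]):
        rows, cols = np.nonzero(labels == c)
        take = min(n_per_class, len(rows))
        pick = rng.choice(len(rows), size=take, replace=False)
        x, y = grid.rowcol_to_center(rows[pick], cols[pick])
        xs.extend(np.atleast_1d(x))
        ys.extend(np.atleast_1d(y))
        cls.extend([int(c)] * take)
    return SurveyPoints.from_arrays(xs, ys, cls, ["calibration"] * len(xs))


def sample_transects(
    truth: LandscapeTruth,
    n_transects: int = 27,
    length_m: float = 3000.0,
    spacing_m: float = 100.0,
    gps_noise_m: float = 5.0,
    seed: int = 0,
    calibration_fraction: float = 0.5,
) -> SurveyPoints:
    """Sample survey points along straight walks starting near villages.

    Each transect has ``floor(length_m / spacing_m) + 1`` stops (inclusive
    endpoints). Stops are labeled with the true class at the undisturbed
    location, then jittered by isotropic Gaussian GPS noise; roles are
    assigned by a stratified-per-class calibration/groundtruth split.
    Transect segments leaving the study extent are truncated with a warning.
    """
    if spacing_m <= 0:
        raise ValueError("spacing_m must be > 0")
    if length_m < spacing_m:
        raise ValueError("length_m must be >= spacing_m")
    if not 0.0 <= calibration_fraction <= 1.0:
        raise ValueError("calibration_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    grid = truth.patch_raster.grid
    grid.require_metric()
    villages = truth.village_points
    n_stops = int(np.floor(length_m / spacing_m)) + 1

    xs, ys, labels = [], [], []
    truncated = 0
    for t in range(n_transects):
        v = villages.iloc[t % len(villages)]
        # start near (within one stop spacing of) the village point
        start = np.array([v["x"], v["y"]]) + rng.uniform(-spacing_m, spacing_m, 2)
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta)])
        for k in range(n_stops):
            p = start + k * spacing_m * direction
            if not bool(grid.contains(p[0], p[1])):
                truncated += 1
                break  # transect truncated at the study-area edge
            xs.append(p[0])
            ys.append(p[1])
    if truncated:
        warnings.warn(
            f"{truncated} transect(s) truncated at the study-area boundary",
            stacklevel=2,
        )

    xs = np.asarray(xs)
    ys = np.asarray(ys)
    row, col = grid.xy_to_rowcol(xs, ys)
    labels = truth.patch_raster.data[row, col].astype(int)

    if gps_noise_m > 0:
        xs = xs + gps_noise_m * rng.standard_normal(len(xs))
        ys = ys + gps_noise_m * rng.standard_normal(len(ys))
        # clamp jittered points back into the extent
        xmin, ymin, xmax, ymax = grid.extent
        eps = 1e-6 * grid.pixel_size
        xs = np.clip(xs, xmin, xmax - eps)
        ys = np.clip(ys, ymin + eps, ymax)

    roles = np.empty(len(xs), dtype=object)
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        idx = rng.permutation(idx)
        n_cal = int(round(calibration_fraction * len(idx)))
        roles[idx[:n_cal]] = "calibration"
        roles[idx[n_cal:]] = "groundtruth"

    return SurveyPoints.from_arrays(xs, ys, labels, roles)
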