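"""Derived spectral layers and class-separability statistics.

NDVI and the tasseled-cap transformation (TCT) compress the raw bands into
layers on which semi-arid classes separate better than on single bands, and
the M statistic, ``M = |mu_1 - mu_2| / (sigma_1 + sigma_2)``, quantifies how
well a single threshold can split two classes on a given layer (M >= 1 is
the conventional "good separability" cut).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sepmap.classes import PatchClass
from sepmap.grid import Raster, check_aligned
from sepmap.points import SurveyPoints
from sepmap.scene import SEASONS, MultiSeasonScene

TCT_COMPONENTS = ("brightness", "greenness", "wetness")

#: Published at-satellite reflectance TCT coefficients for Landsat 8 OLI,
#: reduced to the red/NIR/MIR (bands 4, 5, 7) subset modeled here.
LANDSAT8_TCT_REDUCED: dict[str, dict[str, float]] = {
    "brightness": {"red": 0.4733, "nir": 0.5599, "mir": 0.1872},
    "greenness": {"red": -0.5424, "nir": 0.7276, "mir": -0.1608},
    "wetness": {"red": 0.3283, "nir": 0.3407, "mir": -0.4559},
}

#: Full six-band Landsat 8 OLI table, accepted when full scenes are supplied.
LANDSAT8_TCT_FULL: dict[str, dict[str, float]] = {
    "brightness": {
        "blue": 0.3029, "green": 0.2786, "red": 0.4733,
        "nir": 0.5599, "swir1": 0.5080, "mir": 0.1872,
    },
    "greenness": {
        "blue": -0.2941, "green": -0.2430, "red": -0.5424,
        "nir": 0.7276, "swir1": 0.0713, "mir": -0.1608,
    },
    "wetness": {
        "blue": 0.1511, "green": 0.1973, "red": 0.3283,
        "nir": 0.3407, "swir1": -0.7117, "mir": -0.4559,
    },
}


def ndvi(red: Raster, nir: Raster) -> Raster:
    """Normalized difference vegetation index, (NIR - red) / (NIR + red).

    Pixels where the denominator is zero, or where either input is nodata,
    are set to NaN nodata.
    """
    check_aligned(red, nir)
    r = np.asarray(red.data, dtype=float)
    n = np.asarray(nir.data, dtype=float)
    denom = n + r
    valid = red.mask & nir.mask & (denom != 0)
    out = np.full(r.shape, np.nan)
    np.divide(n - r, denom, out=out, where=valid)
    return Raster(out, red.grid, nodata=np.nan)


def tasseled_cap(
    scene: MultiSeasonScene,
    coefficients: dict[str, dict[str, float]] | None = None,
) -> dict[str, Raster]:
    """Per-season brightness/greenness/wetness linear combinations.

    Every band present in the scene must have a coefficient in every
    component; returns ``{"brightness_dry": Raster, ...}`` (six rasters for
    a two-season scene). Nodata pixels in any input band propagate.
    """
    coefficients = coefficients or LANDSAT8_TCT_REDUCED
    out: dict[str, Raster] = {}
    grid = scene.grid
    for season in SEASONS:
        season_bands = {
            name.rsplit("_", 1)[0]: r
            for name, r in scene.layers.items()
            if name.endswith(f"_{season}") and name.count("_") == 1
            and name.rsplit("_", 1)[0] not in ("ndvi",) + TCT_COMPONENTS
        }
        if not season_bands:
            continue
        valid = np.ones(grid.shape, dtype=bool)
        for r in season_bands.values():
            valid &= r.mask
        for comp in TCT_COMPONENTS:
            weights = coefficients[comp]
            missing = set(season_bands) - set(weights)
            if missing:
                raise ValueError(
                    f"missing {comp} coefficient for band(s) {sorted(missing)}"
                )
            acc = np.zeros(grid.shape, dtype=float)
            for band, r in season_bands.items():
                acc += weights[band] * np.asarray(r.data, dtype=float)
            acc[~valid] = np.nan
            out[f"{comp}_{season}"] = Raster(acc, grid, nodata=np.nan)
    return out


def add_derived_layers(
    scene: MultiSeasonScene,
    coefficients: dict[str, dict[str, float]] | None = None,
) -> MultiSeasonScene:
    """Attach per-season NDVI and TCT layers to the scene (in place)."""
    for season in SEASONS:
        red_name, nir_name = f"red_{season}", f"nir_{season}"
        if red_name in scene and nir_name in scene:
            scene.add(f"ndvi_{season}", ndvi(scene[red_name], scene[nir_name]))
    for name, raster in tasseled_cap(scene, coefficients).items():
        scene.add(name, raster)
    return scene


@dataclass(frozen=True)
class ClassSignature:
    """Sample mean/std of one class on one layer, from calibration points."""

    class_code: int
    layer: str
    n: int
    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("signature needs n >= 2 calibration points")
        if self.std < 0:
            raise ValueError("signature std must be >= 0")


def class_signatures(
    layers: dict[str, Raster],
    points: SurveyPoints,
    role: str = "calibration",
) -> list[ClassSignature]:
    """Per class x layer sample statistics at point locations.

    Uses nearest-pixel lookup and the n-1 (sample) standard deviation.
    Classes with fewer than two usable points on a layer are reported via a
    warning and skipped.
    """
    pts = points.subset(role) if role in set(points.df["role"]) else points
    if len(pts) == 0:
        raise ValueError(f"no points with role {role!r}")
    x, y = pts.xy
    labels = pts.labels
    sigs: list[ClassSignature] = []
    skipped: set[int] = set()
    for layer_name, raster in layers.items():
        vals = raster.sample(x, y).astype(float)
        if raster.nodata is not None:
            if np.issubdtype(np.asarray(raster.nodata).dtype, np.floating) and np.isnan(
                raster.nodata
            ):
                ok = ~np.isnan(vals)
            else:
                ok = vals != raster.nodata
        else:
            ok = np.ones(len(vals), dtype=bool)
        for c in np.unique(labels):
            sel = (labels == c) & ok
            n = int(sel.sum())
            if n < 2:
                skipped.add(int(c))
                continue
            v = vals[sel]
            sigs.append(
                ClassSignature(
                    class_code=int(c),
                    layer=layer_name,
                    n=n,
                    mean=float(np.mean(v)),
                    std=float(np.std(v, ddof=1)),
                )
            )
    if skipped:
        names = sorted(PatchClass(c).label for c in skipped)
        warnings.warn(f"classes with < 2 calibration points skipped: {names}", stacklevel=2)
    return sigs


def m_statistic(a: ClassSignature, b: ClassSignature) -> float:
    """Spectral separability M = |mean_a - mean_b| / (std_a + std_b).

    With a zero denominator: 0 for equal means (indistinguishable), +inf for
    unequal means (perfectly separable point masses).
    """
    if a.layer != b.layer:
        raise ValueError(f"signatures on different layers: {a.layer} vs {b.layer}")
    gap = abs(a.mean - b.mean)
    denom = a.std + b.std
    if denom == 0:
        return 0.0 if gap == 0 else float("inf")
    return gap / denom


class SeparabilityMatrix:
    """Symmetric per-layer, per-class-pair table of M values."""

    def __init__(self, signatures: list[ClassSignature]):
        self._sig: dict[tuple[str, int], ClassSignature] = {
            (s.layer, s.class_code): s for s in signatures
        }
        self._m: dict[tuple[str, int, int], float] = {}
        by_layer: dict[str, list[ClassSignature]] = {}
        for s in signatures:
            by_layer.setdefault(s.layer, []).append(s)
        for layer_name, sigs in by_layer.items():
            for i, a in enumerate(sigs):
                for b in sigs[i + 1 :]:
                    key = (layer_name, *sorted((a.class_code, b.class_code)))
                    self._m[key] = m_statistic(a, b)

    @property
    def layers(self) -> list[str]:
        return sorted({layer for layer, _ in self._sig})

    def signature(self, layer: str, class_code: int) -> ClassSignature:
        return self._sig[(layer, class_code)]

    def m(self, layer: str, a: int, b: int) -> float:
        if a == b:
            return 0.0
        return self._m[(layer, *sorted((a, b)))]

    def has(self, layer: str, class_code: int) -> bool:
        return (layer, class_code) in self._sig

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"layer": layer, "class_a": a, "class_b": b, "m": m}
            for (layer, a, b), m in sorted(self._m.items())
        ]
        return pd.DataFrame(rows, columns=["layer", "class_a", "class_b", "m"])


def signatures_to_frame(signatures: list[ClassSignature]) -> pd.DataFrame:
    """Signature table as (class, layer, n, mean, std) for delimited export."""
    return pd.DataFrame(
        [
            {
                "class": PatchClass(s.class_code).label,
                "layer": s.layer,
                "n": s.n,
                "mean": s.mean,
                "std": s.std,
            }
            for s in signatures
        ]
    )
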