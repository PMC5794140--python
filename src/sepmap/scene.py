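"""Multi-season spectral scene container.

The classifier works from two co-registered satellite scenes — one dry
season, one rainy season — reduced to the three bands that matter for
separating sparsely vegetated semi-arid classes: red, near-infrared (NIR)
and mid-infrared (MIR). Derived layers (NDVI, tasseled-cap components) are
attached to the same container under ``"<layer>_<season>"`` names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sepmap.grid import GridGeometry, Raster, check_aligned

SEASONS = ("dry", "rainy")
BANDS = ("red", "nir", "mir")


@dataclass
class MultiSeasonScene:
    """Aligned dry + rainy season band stacks plus derived index layers.

    ``layers`` maps names like ``"red_dry"``, ``"ndvi_rainy"``,
    ``"brightness_dry"`` to :class:`~sepmap.grid.Raster` objects sharing one
    grid. A shared boolean nodata mask (True = valid) propagates to every
    derived layer.
    """

    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layers:
            check_aligned(*self.layers.values())

    @property
    def grid(self) -> GridGeometry:
        if not self.layers:
            raise ValueError("scene has no layers")
        return next(iter(self.layers.values())).grid

    @property
    def valid_mask(self) -> np.ndarray:
        """True where every band layer is valid."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            mask &= r.mask
        return mask

    def add(self, name: str, raster: Raster) -> None:
        if self.layers:
            check_aligned(next(iter(self.layers.values())), raster)
        self.layers[name] = raster

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def band(self, band: str, season: str) -> Raster:
        return self.layers[f"{band}_{season}"]

    @classmethod
    def from_band_arrays(
        cls,
        grid: GridGeometry,
        arrays: dict[tuple[str, str], np.ndarray],
        nodata: float = np.nan,
    ) -> "MultiSeasonScene":
        """Build a scene from {(season, band): 2-D array} pairs."""
        scene = cls()
        for (season, band), arr in arrays.items():
            if season not in SEASONS or band not in BANDS:
                raise ValueError(f"unknown season/band pair {(season, band)!r}")
            scene.add(f"{band}_{season}", Raster(np.asarray(arr, float), grid, nodata))
        return scene
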