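"""Social-ecological patch vocabulary and stable integer class codes.

Six social-ecological patches (bare soil, depression, field, forest,
homestead, shrubland) plus the two plain land covers water and urban land,
which are mapped but carry no livelihood-benefit scores. Fallow is
deliberately absent: its spectral signature overlaps every other vegetated
class and it cannot be mapped from two-season mid-resolution imagery.

Codes are fixed (1..8, 0 = nodata) so serialized patch maps are stable
across runs and tools.
"""

from __future__ import annotations

from enum import IntEnum


class PatchClass(IntEnum):
    """Integer-coded landscape classes. 0 is reserved for nodata."""

    BARE_SOIL = 1
    DEPRESSION = 2
    FIELD = 3
    FOREST = 4
    HOMESTEAD = 5
    SHRUBLAND = 6
    WATER = 7
    URBAN = 8

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "PatchClass":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown patch class label: {label!r}") from None


NODATA_CODE = 0

#: water and urban are land covers, not social-ecological patches
LAND_COVER_CLASSES = frozenset({PatchClass.WATER, PatchClass.URBAN})

#: the six social-ecological patches proper
PATCH_CLASSES = tuple(c for c in PatchClass if c not in LAND_COVER_CLASSES)

ALL_CLASSES = tuple(PatchClass)

#: code -> label legend, including nodata, for serialized maps
LEGEND = {NODATA_CODE: "nodata", **{int(c): c.label for c in PatchClass}}
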