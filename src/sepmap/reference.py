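"""Reported provincial-scale results used for arithmetic cross-checks.

Landcover composition and buffered ("relative") accuracies reported for the
two ~6000 km^2 study areas in northern Burkina Faso where this mapping
method was originally applied (study area 1: Yatenga/Zondoma/Sourou
provinces; study area 2: Sanmatenga/Bam). Values are percentages of the
mapped landscape. Urban land was not assessed for accuracy (no groundtruth
points inside towns).

Four patches — bare soil, depression, field and homestead — were mapped at
81-96% relative accuracy; the share of the landscape they jointly cover
("well-mapped cover") is the headline figure of how much of each study area
the method resolves reliably.
"""

from __future__ import annotations

STUDY_AREA_COMPOSITION: dict[int, dict[str, float]] = {
    1: {
        "bare_soil": 10.9,
        "depression": 6.0,
        "field": 50.1,
        "forest": 0.4,
        "homestead": 2.8,
        "shrubland": 29.1,
        "water": 0.2,
        "urban": 0.5,
    },
    2: {
        "bare_soil": 7.7,
        "depression": 7.5,
        "field": 71.2,
        "forest": 0.5,
        "homestead": 5.2,
        "shrubland": 6.4,
        "water": 1.1,
        "urban": 0.4,
    },
}

STUDY_AREA_RELATIVE_ACCURACY: dict[int, dict[str, float]] = {
    1: {
        "bare_soil": 90.0,
        "depression": 83.3,
        "field": 86.3,
        "forest": 33.3,
        "homestead": 91.5,
        "shrubland": 50.0,
        "water": 93.8,
        "overall": 74.4,
    },
    2: {
        "bare_soil": 96.0,
        "depression": 87.2,
        "field": 81.0,
        "forest": 25.0,
        "homestead": 95.2,
        "shrubland": 11.4,
        "water": 100.0,
        "overall": 77.8,
    },
}

#: the four patches mapped at 81-96% relative accuracy in both study areas
WELL_MAPPED_CLASSES = ("bare_soil", "depression", "field", "homestead")


def well_mapped_cover_percent(study_area: int) -> float:
    """Joint landcover share (%) of the four reliably mapped patches."""
    comp = STUDY_AREA_COMPOSITION[study_area]
    return float(sum(comp[c] for c in WELL_MAPPED_CLASSES))
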