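"""Buffered "relative" accuracy, confusion matrix, landcover composition.

The headline accuracy measure is deliberately tolerant of small location
errors: a groundtruth point counts as correct if a disk of radius
``buffer_m`` (default 15 m, half a pixel) around it overlaps at least one
pixel mapped to the point's true class. "Overlaps" means positive-area
intersection of the open disk with the open pixel cell — equivalently, the
Euclidean distance from the point to the closed cell rectangle is strictly
less than the buffer radius; touching at a corner or edge does not count.
At ``buffer_m = 0`` the measure degenerates to plain point-in-pixel
accuracy, so buffered accuracy is always >= point accuracy and
non-decreasing in the buffer radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from sepmap.classes import PatchClass
from sepmap.grid import Raster
from sepmap.points import SurveyPoints


@dataclass
class RelativeAccuracy:
    """Per-class and pooled buffered accuracies (percent)."""

    buffer_m: float
    per_class: dict[int, float]
    n_per_class: dict[int, int]
    overall: float  # point-pooled (primary)
    mean_of_classes: float  # unweighted class mean (secondary)
    excluded_classes: list[int] = dc_field(default_factory=list)


def _point_correct_buffered(
    patch_map: Raster, x: float, y: float, true_class: int, buffer_m: float
) -> bool:
    grid = patch_map.grid
    s = grid.pixel_size
    halo = int(np.ceil(buffer_m / s)) + 1
    r0, c0 = (int(v) for v in grid.xy_to_rowcol(x, y))
    rows = range(max(r0 - halo, 0), min(r0 + halo + 1, grid.n_rows))
    cols = range(max(c0 - halo, 0), min(c0 + halo + 1, grid.n_cols))
    for r in rows:
        for c in cols:
            if patch_map.data[r, c] != true_class:
                continue
            xmin, ymin, xmax, ymax = grid.cell_bounds(r, c)
            dx = max(xmin - x, 0.0, x - xmax)
            dy = max(ymin - y, 0.0, y - ymax)
            if np.hypot(dx, dy) < buffer_m:  # open disk, positive-area overlap
                return True
    return False


def relative_accuracy(
    patch_map: Raster,
    points: SurveyPoints,
    buffer_m: float = 15.0,
    exclude_classes: tuple[int, ...] = (),
) -> RelativeAccuracy:
    """Buffered accuracy of a patch map against groundtruth points.

    Classes listed in ``exclude_classes`` (and classes with no groundtruth
    points) are left out of the per-class table and the pooled total; they
    are recorded in ``excluded_classes``.
    """
    if buffer_m < 0:
        raise ValueError("buffer_m must be >= 0")
    patch_map.grid.require_metric()
    pts = points.subset("groundtruth") if "groundtruth" in set(points.df["role"]) else points
    x, y = pts.xy
    labels = pts.labels
    keep = ~np.isin(labels, np.asarray(exclude_classes, dtype=int))
    x, y, labels = x[keep], y[keep], labels[keep]
    if len(labels) == 0:
        raise ValueError("no usable groundtruth points")

    if buffer_m == 0:
        correct = patch_map.sample(x, y).astype(int) == labels
    else:
        correct = np.array(
            [
                _point_correct_buffered(patch_map, xi, yi, int(ci), buffer_m)
                for xi, yi, ci in zip(x, y, labels)
            ]
        )

    per_class: dict[int, float] = {}
    n_per_class: dict[int, int] = {}
    for c in np.unique(labels):
        sel = labels == c
        per_class[int(c)] = 100.0 * float(correct[sel].mean())
        n_per_class[int(c)] = int(sel.sum())
    return RelativeAccuracy(
        buffer_m=buffer_m,
        per_class=per_class,
        n_per_class=n_per_class,
        overall=100.0 * float(correct.mean()),
        mean_of_classes=float(np.mean(list(per_class.values()))),
        excluded_classes=sorted(set(int(c) for c in exclude_classes)),
    )


def confusion_matrix(
    patch_map: Raster, points: SurveyPoints
) -> tuple[pd.DataFrame, pd.Series, pd.Series, float]:
    """Point-in-pixel cross-tabulation with producer's and user's accuracies.

    Returns ``(matrix, producers, users, overall)`` where the matrix has
    predicted classes as rows and groundtruth classes as columns, producer's
    accuracy is diagonal/column-sum (recall) and user's accuracy is
    diagonal/row-sum (precision), all in percent.
    """
    pts = points.subset("groundtruth") if "groundtruth" in set(points.df["role"]) else points
    x, y = pts.xy
    if not np.all(patch_map.grid.contains(x, y)):
        raise ValueError("groundtruth point outside map extent")
    predicted = patch_map.sample(x, y).astype(int)
    truth = pts.labels

    codes = sorted(set(predicted) | set(truth))
    names = [PatchClass(c).label if c != 0 else "nodata" for c in codes]
    matrix = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for p, t in zip(predicted, truth):
        matrix.iloc[codes.index(p), codes.index(t)] += 1
    matrix.index.name = "predicted"
    matrix.columns.name = "groundtruth"

    diag = pd.Series(np.diag(matrix.to_numpy()), index=names, dtype=float)
    col_sums = matrix.sum(axis=0).astype(float)
    row_sums = matrix.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        producers = (100.0 * diag / col_sums).where(col_sums > 0)
        users = (100.0 * diag / row_sums).where(row_sums > 0)
    overall = 100.0 * float(diag.sum()) / float(len(truth))
    return matrix, producers, users, overall


def landcover_composition(patch_map: Raster) -> dict[str, float]:
    """Percent of non-nodata pixels per class, water and urban included."""
    valid = patch_map.mask
    total = int(valid.sum())
    if total == 0:
        raise ValueError("patch map has no valid pixels")
    codes = np.asarray(patch_map.data)[valid].astype(int)
    counts = np.bincount(codes, minlength=int(max(PatchClass)) + 1)
    return {
        c.label: 100.0 * counts[int(c)] / total
        for c in PatchClass
        if counts[int(c)] > 0
    }


@dataclass
class AccuracyReport:
    """Everything a map-accuracy table needs, in one place."""

    composition: dict[str, float]
    relative: RelativeAccuracy
    confusion: pd.DataFrame
    producers: pd.Series
    users: pd.Series
    overall_point_accuracy: float

    def to_dict(self) -> dict:
        label = lambda c: PatchClass(c).label  # noqa: E731
        return {
            "buffer_m": self.relative.buffer_m,
            "landcover_percent": self.composition,
            "relative_accuracy_percent": {
                label(c): v for c, v in self.relative.per_class.items()
            },
            "n_groundtruth_per_class": {
                label(c): v for c, v in self.relative.n_per_class.items()
            },
            "excluded_classes": [label(c) for c in self.relative.excluded_classes],
            "overall_relative_accuracy_percent": self.relative.overall,
            "mean_class_relative_accuracy_percent": self.relative.mean_of_classes,
            "overall_point_accuracy_percent": self.overall_point_accuracy,
            "producers_accuracy_percent": {
                k: (None if pd.isna(v) else v) for k, v in self.producers.items()
            },
            "users_accuracy_percent": {
                k: (None if pd.isna(v) else v) for k, v in self.users.items()
            },
            "confusion_matrix": {
                "predicted": list(self.confusion.index),
                "groundtruth": list(self.confusion.columns),
                "counts": self.confusion.to_numpy().tolist(),
            },
        }

    def composition_table(self) -> pd.DataFrame:
        """Class, landcover %, relative accuracy % (None where excluded)."""
        rows = []
        rel = {PatchClass(c).label: v for c, v in self.relative.per_class.items()}
        for cls, share in self.composition.items():
            rows.append(
                {
                    "class": cls,
                    "landcover_percent": share,
                    "relative_accuracy_percent": rel.get(cls),
                }
            )
        return pd.DataFrame(rows)


def assess(
    patch_map: Raster,
    points: SurveyPoints,
    buffer_m: float = 15.0,
) -> AccuracyReport:
    """Full accuracy report.

    Urban land has no groundtruth accuracy (field walks do not survey town
    interiors), so urban points are excluded from the buffered-accuracy
    table; water is assessed like any patch.
    """
    rel = relative_accuracy(
        patch_map, points, buffer_m, exclude_classes=(int(PatchClass.URBAN),)
    )
    matrix, producers, users, overall = confusion_matrix(patch_map, points)
    return AccuracyReport(
        composition=landcover_composition(patch_map),
        relative=rel,
        confusion=matrix,
        producers=producers,
        users=users,
        overall_point_accuracy=overall,
    )
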