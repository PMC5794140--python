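"""Survey (transect) point sets used for calibration and groundtruthing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLES = ("calibration", "groundtruth")


@dataclass
class SurveyPoints:
    """Field points with a known true class and a role.

    Backed by a DataFrame with columns ``x``, ``y`` (projected meters),
    ``true_class`` (integer class code) and ``role`` (``"calibration"`` or
    ``"groundtruth"``). The two roles partition the set.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"x", "y", "true_class", "role"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"SurveyPoints missing columns: {sorted(missing)}")
        bad = set(self.df["role"].unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, role: str) -> "SurveyPoints":
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return SurveyPoints(self.df[self.df["role"] == role].reset_index(drop=True))

    @property
    def calibration(self) -> "SurveyPoints":
        return self.subset("calibration")

    @property
    def groundtruth(self) -> "SurveyPoints":
        return self.subset("groundtruth")

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.df["x"].to_numpy(float), self.df["y"].to_numpy(float)

    @property
    def labels(self) -> np.ndarray:
        return self.df["true_class"].to_numpy(int)

    @classmethod
    def from_arrays(cls, x, y, true_class, role) -> "SurveyPoints":
        return cls(
            pd.DataFrame(
                {
                    "x": np.asarray(x, float),
                    "y": np.asarray(y, float),
                    "true_class": np.asarray(true_class, int),
                    "role": np.asarray(role, object),
                }
            )
        )
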