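"""Five-class localization profiles from section percentages.

A stage-level profile (percentages in sections A..E summing to 100) is
assigned, in fixed order, to extreme animal, extreme vegetal, animal,
vegetal, or central, falling through to "undefined".  Threshold defaults
(60 % in an extreme section, 60 % in a pole pair, 70 % in the central
core with a unique interior maximum) are configurable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import PCT_COLUMNS

CLASS_LABELS = (
    "extreme_animal",
    "animal",
    "central",
    "vegetal",
    "extreme_vegetal",
    "undefined",
)

#: display names used in per-stage summary tallies
TALLY_NAMES = {
    "extreme_animal": "Extreme animal",
    "animal": "Animal",
    "central": "Center",
    "vegetal": "Vegetal",
    "extreme_vegetal": "Extreme vegetal",
    "undefined": "Undefined",
}

MIRROR = {
    "extreme_animal": "extreme_vegetal",
    "extreme_vegetal": "extreme_animal",
    "animal": "vegetal",
    "vegetal": "animal",
    "central": "central",
    "undefined": "undefined",
}


@dataclass(frozen=True)
class ClassThresholds:
    extreme_pole_min_pct: float = 60.0
    pole_pair_min_pct: float = 60.0
    central_core_min_pct: float = 70.0

    def __post_init__(self) -> None:
        for v in (self.extreme_pole_min_pct, self.pole_pair_min_pct,
                  self.central_core_min_pct):
            if not 0 < v <= 100:
                raise ValueError("class thresholds must lie in (0, 100]")


def classify_profile(
    percentages, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Class label for one five-section percentage vector (A..E)."""
    p = np.asarray(percentages, float)
    if p.shape != (5,):
        raise ValueError("expected five section percentages")
    if (p < 0).any():
        raise ValueError("negative percentage")
    if abs(p.sum() - 100.0) > 1e-6:
        raise ValueError("percentages must sum to 100")
    pa, pb, pc, pd_, pe = p
    t = thresholds
    if pa >= t.extreme_pole_min_pct:
        return "extreme_animal"
    if pe >= t.extreme_pole_min_pct:
        return "extreme_vegetal"
    if pa + pb >= t.pole_pair_min_pct:
        return "animal"
    if pd_ + pe >= t.pole_pair_min_pct:
        return "vegetal"
    if pb + pc + pd_ >= t.central_core_min_pct and pc > max(pa, pb, pd_, pe):
        return "central"
    return "undefined"


def classify_all(
    profiles: pd.DataFrame, thresholds: ClassThresholds = ClassThresholds()
) -> pd.DataFrame:
    """Classify a stage-profile table (columns pct_A..pct_E) row by row.

    Rows with missing percentages (no informative oocyte) are labeled
    "undefined".  Returns the input with a ``class_label`` column added.
    """
    out = profiles.copy()
    labels = []
    for row in out[PCT_COLUMNS].to_numpy(float):
        if np.isnan(row).any():
            labels.append("undefined")
        else:
            labels.append(classify_profile(row, thresholds))
    out["class_label"] = labels
    return out


def class_tally(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-stage class counts (profile-category summary layout)."""
    tab = (
        classified.groupby(["stage", "class_label"], sort=False)
        .size()
        .unstack("stage", fill_value=0)
    )
    tab = tab.reindex(list(TALLY_NAMES), fill_value=0)
    tab.index = [TALLY_NAMES[c] for c in tab.index]
    tab.index.name = "profile"
    return tab
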