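"""Xenograft tumor-growth summaries and group comparisons.

Caliper measurements (length, width per animal per day) become volumes
via the standard ellipsoid approximation V = L * W^2 / 2 (mm^3); group
trajectories are summarized as mean +/- SD with the per-day number of
surviving animals, and treatment effects are reported as percent
reduction of the group-mean volume versus vehicle plus a two-sample
Student's t-test (Welch optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComparisonError, ValidationError

__all__ = [
    "TumorMeasurement",
    "tumor_volume",
    "percent_reduction",
    "growth_summary",
    "compare_groups",
]


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement; width > length is auto-swapped (caliper
    convention puts the longer axis first)."""

    animal_id: str
    day: int
    length: float
    width: float
    group: str

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValidationError("length and width must be > 0")
        if self.width > self.length:
            warnings.warn(
                f"animal {self.animal_id} day {self.day}: width > length, swapping",
                stacklevel=2,
            )
            length, width = self.width, self.length
            object.__setattr__(self, "length", length)
            object.__setattr__(self, "width", width)

    @property
    def volume(self) -> float:
        return tumor_volume(self.length, self.width)


def tumor_volume(length, width):
    """V = length * width^2 / 2, in mm^3 for mm inputs."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValidationError("length and width must be > 0")
    out = length * width**2 / 2.0
    return float(out) if out.ndim == 0 else out


def percent_reduction(mean_control: float, mean_treated: float) -> float:
    """Percent reduction of treated group-mean volume vs control."""
    if mean_control <= 0:
        raise ValidationError(f"mean_control must be > 0, got {mean_control}")
    return 100.0 * (mean_control - mean_treated) / mean_control


def growth_summary(measurements: Sequence[TumorMeasurement]) -> pd.DataFrame:
    """Per (group, day) mean/SD volume and number of animals measured.

    Animals that drop out mid-study simply stop contributing; no
    imputation, matching the changing-n convention of growth plots.
    """
    rows = [
        {"group": m.group, "day": m.day, "animal_id": m.animal_id, "volume": m.volume}
        for m in measurements
    ]
    if not rows:
        return pd.DataFrame(columns=["group", "day", "mean_volume", "sd_volume", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "day"])["volume"]
        .agg(mean_volume="mean", sd_volume="std", n="count")
        .reset_index()
    )
    out["sd_volume"] = out["sd_volume"].fillna(0.0)
    return out


def compare_groups(
    volumes_by_group: Mapping[str, Sequence[float]],
    control: str = "vehicle",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test of each treatment group against the control.

    Equal-variance Student's t by default; ``equal_var=False`` gives
    Welch.  Returns a DataFrame with one row per contrast: group, n per
    arm, mean volumes, percent reduction, t and two-sided p.
    """
    if control not in volumes_by_group:
        raise ComparisonError(f"control group {control!r} not present")
    ctrl = np.asarray(volumes_by_group[control], dtype=float)
    if len(ctrl) < 2:
        raise ComparisonError(f"control group has {len(ctrl)} animals; need >= 2")
    rows = []
    for group, vols in volumes_by_group.items():
        if group == control:
            continue
        v = np.asarray(vols, dtype=float)
        if len(v) < 2:
            raise ComparisonError(f"group {group!r} has {len(v)} animals; need >= 2")
        t, p = stats.ttest_ind(v, ctrl, equal_var=equal_var)
        if not np.isfinite(t) and np.mean(v) == np.mean(ctrl):
            t, p = 0.0, 1.0  # zero difference with zero pooled variance
        rows.append(
            {
                "group": group,
                "control": control,
                "n_group": len(v),
                "n_control": len(ctrl),
                "mean_group": float(np.mean(v)),
                "mean_control": float(np.mean(ctrl)),
                "percent_reduction": percent_reduction(
                    float(np.mean(ctrl)), float(np.mean(v))
                ),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
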