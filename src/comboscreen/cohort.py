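"""Cohort-level aggregation of single-agent response across cell lines.

A screened cohort is summarized by per-line AUC and IC50; lines are
called *sensitive* when their IC50 falls below 20% of the cohort median
IC50 (computed over uncensored fits only — censored bounds would bias
the median upward), and *resistant* otherwise.  Censored lines are
always resistant: their bound exceeds any threshold below max_conc.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError

__all__ = ["CohortRecord", "classify_sensitivity", "cohort_auc_table"]

SENSITIVITY_FRACTION = 0.2  # sensitive iff IC50 < 20% of the median uncensored IC50


@dataclass(frozen=True)
class CohortRecord:
    cell_line: str
    tissue_class: str  # tumor | matched_normal
    auc: float
    ic50: float
    ic50_censored: bool = False
    sensitivity: str = "unclassified"


def classify_sensitivity(
    records: Sequence[CohortRecord], fraction: float = SENSITIVITY_FRACTION
) -> List[CohortRecord]:
    """Label each record sensitive/resistant by the <20%-of-median-IC50 rule."""
    uncensored = [r.ic50 for r in records if not r.ic50_censored]
    if len(uncensored) < 3:
        raise ClassificationError(
            f"need >= 3 uncensored IC50s to classify, got {len(uncensored)}"
        )
    threshold = fraction * float(np.median(uncensored))
    out = []
    for r in records:
        if r.ic50_censored:
            label = "resistant"
        else:
            label = "sensitive" if r.ic50 < threshold else "resistant"
        out.append(replace(r, sensitivity=label))
    return out


def cohort_auc_table(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Records sorted by AUC with tissue-class annotation.

    ``above_no_effect`` marks lines at or beyond the no-effect reference
    AUC = 1 (drug-induced stimulation of metabolic rate).
    """
    rows = [
        {
            "cell_line": r.cell_line,
            "auc": r.auc,
            "tissue_class": r.tissue_class,
            "sensitivity": r.sensitivity,
            "ic50": r.ic50,
            "ic50_censored": r.ic50_censored,
            "above_no_effect": r.auc >= 1.0,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_line",
            "auc",
            "tissue_class",
            "sensitivity",
            "ic50",
            "ic50_censored",
            "above_no_effect",
        ],
    )
    return df.sort_values("auc", kind="mergesort").reset_index(drop=True)
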