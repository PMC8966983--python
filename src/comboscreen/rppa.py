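"""Differential-affinity analysis of reverse-phase protein arrays.

The RPPA readout is a matrix of normalized log2 affinities, antibodies
by samples, with per-antibody validation status from the array core
facility and per-sample experimental metadata (cell line, trametinib
sensitivity class, drug vs vehicle treatment, timepoint).  Analysis
follows the standard small-n proteomics workflow:

1. keep only "validated" antibodies ("use with caution" and other
   statuses are excluded from the primary analysis);
2. per antibody, compare drug vs vehicle within a stratum with a
   moderated t-test: residual variances are shrunk toward a common
   prior estimated by empirical Bayes from the across-antibody variance
   distribution (moment matching of the log-variances with a trigamma
   inversion, i.e. a scaled inverse-chi-square prior);
3. control the FDR with Benjamini-Hochberg, calling an antibody
   significant at FDR < 0.05;
4. compare significant sets across strata (e.g. 24 h vs 72 h, sensitive
   vs resistant), stratified by direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import EmptyAnalysisError, StratumError, ValidationError

__all__ = [
    "RPPAMatrix",
    "filter_validated",
    "moderated_t_test",
    "estimate_variance_prior",
    "bh_adjust",
    "set_comparison",
]

SAMPLE_META_COLUMNS = ("cell_line", "sensitivity", "treatment", "timepoint")


@dataclass
class RPPAMatrix:
    """Antibody x sample matrix of normalized log2 affinities.

    ``antibody_meta`` holds per-antibody ``status`` (validated / caution /
    other); ``sample_meta`` holds per-sample cell_line, sensitivity
    (sensitive / resistant), treatment (drug / vehicle) and timepoint.
    """

    values: pd.DataFrame
    antibody_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValidationError("RPPA values contain missing entries")
        if not self.values.index.equals(self.antibody_meta.index):
            if set(self.values.index) != set(self.antibody_meta.index):
                raise ValidationError("antibody_meta index does not match values rows")
            self.antibody_meta = self.antibody_meta.loc[self.values.index]
        if not self.values.columns.equals(self.sample_meta.index):
            if set(self.values.columns) != set(self.sample_meta.index):
                raise ValidationError("sample_meta index does not match values columns")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        missing = [c for c in SAMPLE_META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValidationError(f"sample_meta lacks columns: {missing}")
        if "status" not in self.antibody_meta.columns:
            raise ValidationError("antibody_meta lacks a 'status' column")

    @property
    def n_antibodies(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, mask) -> "RPPAMatrix":
        cols = self.sample_meta.index[mask]
        return RPPAMatrix(
            values=self.values[cols],
            antibody_meta=self.antibody_meta,
            sample_meta=self.sample_meta.loc[cols],
        )


def filter_validated(matrix: RPPAMatrix) -> RPPAMatrix:
    """Keep only antibodies with status 'validated'.

    'use with caution' antibodies (e.g. the MAPK phospho-antibody in the
    trametinib screen) and any other status are dropped from the primary
    analysis.
    """
    keep = matrix.antibody_meta["status"] == "validated"
    if not keep.any():
        raise EmptyAnalysisError("no validated antibodies remain after filtering")
    return RPPAMatrix(
        values=matrix.values.loc[keep.values],
        antibody_meta=matrix.antibody_meta.loc[keep.values],
        sample_meta=matrix.sample_meta,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """(prior_df, prior_var) for the scaled inverse-chi-square variance prior.

    Moment matching on the log variances: for s2 ~ s0^2 * chi^2_df / df
    scaled by an F-tail with df0, the mean and variance of log(s2)
    involve digamma/trigamma terms; matching them gives the prior df by
    trigamma inversion and the prior variance from the mean.  Returns
    ``inf`` prior df (complete shrinkage to a single variance) when the
    observed spread of log-variances is no larger than sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0):
        raise ValidationError("variances must be >= 0")
    n = len(s2)
    if n < 2:
        return 0.0, float(np.mean(s2)) if n else 0.0
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df0 = 2.0 * _trigamma_inverse(evar)
        s20 = float(
            np.exp(emean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
        )
    else:
        # spread no wider than sampling noise: shrink completely.  The prior
        # variance is the geometric mean of the observed variances, so that
        # exactly identical variances are a fixed point of the shrinkage.
        df0 = float("inf")
        s20 = float(np.exp(np.mean(z)))
    return df0, s20


def moderated_t_test(
    matrix: RPPAMatrix,
    stratum: Optional[Mapping[str, str]] = None,
    group_col: str = "treatment",
    groups: Tuple[str, str] = ("drug", "vehicle"),
    prior_df: Optional[float] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-antibody empirical-Bayes moderated t-test, group[0] - group[1].

    ``stratum`` restricts samples by metadata equality (e.g.
    ``{"timepoint": "72h"}`` or ``{"sensitivity": "resistant"}``) before
    contrasting ``groups`` of ``group_col``.  ``prior_df`` overrides the
    estimated prior degrees of freedom; 0 disables shrinkage and recovers
    the ordinary equal-variance two-sample t exactly.

    Returns a DataFrame indexed by antibody with columns log_fc, t_mod,
    p, fdr, significant (fdr < ``alpha``) and direction (up/down).
    """
    meta = matrix.sample_meta
    mask = np.ones(len(meta), dtype=bool)
    if stratum:
        for key, val in stratum.items():
            if key not in meta.columns:
                raise ValidationError(f"unknown sample metadata column {key!r}")
            mask &= (meta[key] == val).values
    sub = matrix.select_samples(mask)
    g1 = sub.sample_meta[group_col] == groups[0]
    g2 = sub.sample_meta[group_col] == groups[1]
    n1, n2 = int(g1.sum()), int(g2.sum())
    if n1 < 2 or n2 < 2:
        raise StratumError(
            f"need >= 2 samples per arm in stratum {dict(stratum or {})}; "
            f"got {groups[0]}={n1}, {groups[1]}={n2}"
        )
    x1 = sub.values.loc[:, g1.values].to_numpy(float)
    x2 = sub.values.loc[:, g2.values].to_numpy(float)
    mean_diff = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        df0, s20 = estimate_variance_prior(s2, df_resid)
    elif prior_df == 0:
        df0, s20 = 0.0, 0.0
    else:
        df0 = float(prior_df)
        _, s20 = estimate_variance_prior(s2, df_resid)
    if np.isinf(df0):
        s2_post = np.full_like(s2, s20)
        df_total = np.inf
    else:
        s2_post = (df0 * s20 + df_resid * s2) / (df0 + df_resid)
        # total df capped at the pooled residual df across antibodies
        df_total = min(df_resid + df0, df_resid * len(s2))
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, mean_diff / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log_fc": mean_diff,
            "t_mod": t_mod,
            "p": p,
            "fdr": fdr,
            "significant": fdr < alpha,
            "direction": np.where(mean_diff >= 0, "up", "down"),
        },
        index=sub.values.index,
    )
    out.index.name = "antibody"
    out.attrs["prior_df"] = df0
    out.attrs["prior_var"] = s20
    out.attrs["n_per_arm"] = (n1, n2)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_(i) = min_{j >= i} min(1, m p_(j) / j) over the sorted p-values,
    enforcing monotonicity with a reverse running minimum.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    stepped = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def set_comparison(
    results_by_stratum: Mapping[str, pd.DataFrame]
) -> Dict[str, Dict[str, set]]:
    """Direction-stratified overlap of significant antibodies across strata.

    For each direction (up/down) returns the antibodies significant in
    every stratum (``shared``) and those unique to each stratum
    (``only:<stratum>``), mirroring the Venn-diagram summary of a
    two-timepoint or sensitivity-stratified analysis.
    """
    if len(results_by_stratum) < 2:
        raise ValidationError("set comparison needs at least 2 strata")
    report: Dict[str, Dict[str, set]] = {}
    for direction in ("up", "down"):
        sets = {
            name: set(
                res.index[(res["significant"]) & (res["direction"] == direction)]
            )
            for name, res in results_by_stratum.items()
        }
        shared = set.intersection(*sets.values())
        entry: Dict[str, set] = {"shared": shared}
        for name, s in sets.items():
            others = set.union(*(v for k, v in sets.items() if k != name))
            entry[f"only:{name}"] = s - others
        entry["sizes"] = {name: len(s) for name, s in sets.items()}
        report[direction] = entry
    return report
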