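"""Synergy scoring for drug-combination screens.

Two complementary synergy frameworks are implemented:

* **Chou-Talalay combination index (CI)**, rooted in Loewe additivity.
  At a fixed inhibition level xx, for combination doses (C_A, C_B)
  achieving that effect and single-agent iso-effective doses IC_xx,A and
  IC_xx,B,

      CI = C_A / IC_xx,A + C_B / IC_xx,B

  CI < 1 indicates synergy, CI = 1 additivity (a drug is exactly
  additive with itself), CI > 1 antagonism.  Single agents whose IC50 is
  censored (never reached 50% inhibition in the tested range) contribute
  their bound max_conc, making the CI a lower bound that is excluded
  from optimal-regimen selection.  The dose pair with the minimum
  defined CI over the searched effect levels is the maximal synergistic
  dose, i.e. the optimal regimen.

* **Bliss beta**, rooted in Bliss independence.  With margin inhibitions
  a_i, b_j taken from the embedded single-agent row/column of the grid,
  the Bliss-expected inhibition of an interior cell is
  e_ij = 1 - (1 - a_i)(1 - b_j).  Beta is the least-squares slope
  through the origin of observed versus expected inhibition: 1 is
  additive, > 1 synergistic, < 1 antagonistic.

Concordance between the two frameworks across a panel is summarized by
the Spearman rank correlation of Bliss betas against minimum CIs (the
two scales run in opposite directions, so concordance is a negative
correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import spearmanr

from .dose_response import HillFit, invert_hill
from .errors import PairingError, RegimenUndefinedError, ValidationError
from .gp_surface import GPSurface, find_isoeffect
from .plates import CombinationGrid

__all__ = [
    "CombinationIndexResult",
    "OptimalRegimen",
    "BlissBetaResult",
    "compute_ci",
    "ci_over_grid",
    "min_ci_regimen",
    "compute_bliss_beta",
    "correlate_synergy_metrics",
]

#: Effect (inhibition) levels searched for the minimum CI by default.
DEFAULT_EFFECT_LEVELS: Tuple[float, ...] = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class CombinationIndexResult:
    """CI at one combination dose pair and effect level.

    ``status`` is ``computed`` for a fully defined CI, ``censored_bound``
    when at least one single-agent IC_xx is a censored lower bound (the
    CI is then itself a lower bound), and ``not_reached`` when the
    combination never achieved the effect level (no CI defined).
    """

    effect_level: float
    conc_a: float
    conc_b: float
    ic_xx_a: Optional[float]
    ic_xx_b: Optional[float]
    ci: Optional[float]
    ci_is_lower_bound: bool
    status: str  # computed | censored_bound | not_reached

    def __post_init__(self):
        if self.status not in ("computed", "censored_bound", "not_reached"):
            raise ValidationError(f"invalid status {self.status!r}")
        if (self.ci is not None) != (self.status != "not_reached"):
            raise ValidationError("ci must be defined iff status != not_reached")


@dataclass(frozen=True)
class OptimalRegimen:
    conc_a: float
    conc_b: float
    min_ci: float
    effect_level: float


@dataclass(frozen=True)
class BlissBetaResult:
    beta: float
    n_cells: int


def _single_agent_icxx(fit: HillFit, effect_level: float):
    """(IC_xx, is_censored_bound) for one agent at one inhibition level.

    Inhibition is relative to the no-drug control, so the target
    viability is 1 - effect_level.  A censored fit, or a fit whose lower
    asymptote never reaches the target, contributes the bound max_conc.
    """
    if fit.censored:
        return fit.max_conc, True
    ic = invert_hill(fit, 1.0 - effect_level)
    if not np.isfinite(ic):
        return fit.max_conc, True
    return ic, False


def compute_ci(
    conc_a: float,
    conc_b: float,
    fit_a: HillFit,
    fit_b: HillFit,
    effect_level: float,
) -> CombinationIndexResult:
    """Chou-Talalay CI for a combination dose pair achieving ``effect_level``.

    CI = conc_a / IC_xx,A + conc_b / IC_xx,B, with a zero dose
    contributing nothing.  Censored single agents substitute their bound
    max_conc, flagging the CI as a lower bound.  Scaling both doses by a
    factor scales the CI by the same factor (exact linearity).
    """
    if not (0 < effect_level < 1):
        raise ValidationError(f"effect_level must be in (0, 1), got {effect_level}")
    if conc_a < 0 or conc_b < 0:
        raise ValidationError("combination doses must be >= 0")
    ic_a, cens_a = _single_agent_icxx(fit_a, effect_level)
    ic_b, cens_b = _single_agent_icxx(fit_b, effect_level)
    lower_bound = (cens_a and conc_a > 0) or (cens_b and conc_b > 0)
    ci = 0.0
    if conc_a > 0:
        ci += conc_a / ic_a
    if conc_b > 0:
        ci += conc_b / ic_b
    return CombinationIndexResult(
        effect_level=effect_level,
        conc_a=conc_a,
        conc_b=conc_b,
        ic_xx_a=ic_a,
        ic_xx_b=ic_b,
        ci=ci,
        ci_is_lower_bound=lower_bound,
        status="censored_bound" if lower_bound else "computed",
    )


def ci_over_grid(
    surface: GPSurface,
    fit_a: HillFit,
    fit_b: HillFit,
    effect_levels: Sequence[float] = DEFAULT_EFFECT_LEVELS,
) -> List[CombinationIndexResult]:
    """CI at every iso-effect contour point of the GP surface.

    For each effect level the contour is traced on the posterior mean;
    levels the combination never reaches yield a single ``not_reached``
    record (no CI calculated, honoring the screen's reporting rule).
    """
    results: List[CombinationIndexResult] = []
    for level in effect_levels:
        contour = find_isoeffect(surface, level)
        if not contour.reached:
            results.append(
                CombinationIndexResult(
                    effect_level=level,
                    conc_a=float("nan"),
                    conc_b=float("nan"),
                    ic_xx_a=None,
                    ic_xx_b=None,
                    ci=None,
                    ci_is_lower_bound=False,
                    status="not_reached",
                )
            )
            continue
        for ca, cb in contour.points:
            results.append(compute_ci(ca, cb, fit_a, fit_b, level))
    return results


def min_ci_regimen(results: Sequence[CombinationIndexResult]) -> OptimalRegimen:
    """The dose pair with the smallest fully computed CI.

    Censored lower-bound CIs are excluded (their true CI may be larger);
    ties are broken by the smallest total concentration.  Raises
    :class:`RegimenUndefinedError` when nothing is computable.
    """
    candidates = [r for r in results if r.status == "computed"]
    if not candidates:
        raise RegimenUndefinedError(
            "no computed CI values; effect never reached or all single agents censored"
        )
    best = min(candidates, key=lambda r: (r.ci, r.conc_a + r.conc_b))
    return OptimalRegimen(
        conc_a=best.conc_a,
        conc_b=best.conc_b,
        min_ci=best.ci,
        effect_level=best.effect_level,
    )


def compute_bliss_beta(grid: CombinationGrid) -> BlissBetaResult:
    """Origin-constrained regression of observed on Bliss-expected inhibition.

    Margins come from the embedded single-agent row/column (zero-dose
    axes required).  beta = sum(e * o) / sum(e^2) over interior cells
    with expected inhibition e > 0; exactly 1 when the grid was
    generated under Bliss independence without noise.
    """
    if not grid.has_zero_doses:
        raise ValidationError(
            "Bliss beta needs embedded single-agent margins (zero-dose axes)"
        )
    margin_a = 1.0 - grid.single_agent_margin("a")[1:]  # inhibition of drug A alone
    margin_b = 1.0 - grid.single_agent_margin("b")[1:]
    observed = 1.0 - grid.viabilities[1:, 1:]
    expected = 1.0 - np.outer(1.0 - margin_a, 1.0 - margin_b)
    mask = expected > 0
    if not np.any(mask):
        raise ValidationError("all Bliss-expected inhibitions are zero; beta undefined")
    e = expected[mask]
    o = observed[mask]
    beta = float(np.sum(e * o) / np.sum(e * e))
    return BlissBetaResult(beta=beta, n_cells=int(mask.sum()))


def correlate_synergy_metrics(
    betas: Sequence[float], cis: Sequence[float]
) -> float:
    """Spearman rank correlation between Bliss betas and minimum CIs.

    Entries must be paired by drug pair x cell line.  Ties get average
    ranks.  Synergy raises beta and lowers CI, so concordant panels give
    a negative rho.
    """
    if len(betas) != len(cis):
        raise PairingError(
            f"paired metrics have mismatched lengths: {len(betas)} vs {len(cis)}"
        )
    if len(betas) < 3:
        raise PairingError("need at least 3 paired values")
    rho = spearmanr(np.asarray(betas, float), np.asarray(cis, float)).statistic
    return float(rho)
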