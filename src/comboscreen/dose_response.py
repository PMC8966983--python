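"""Single-agent dose-response analysis.

Curves of normalized viability versus concentration are fitted with a
four-parameter Hill (log-logistic) model

    v(c) = e_inf + (e0 - e_inf) / (1 + (c / ic50)^h)

by least squares on the log10-dose scale, using a gradient-based
optimizer started from a deterministic grid of initial (IC50, slope)
values.  Drugs whose fitted curve never reaches 50% inhibition of the
no-drug control within the tested range are censored: the IC50 is
reported as the inequality IC50 >= max_conc, a flag that downstream
combination-index calculations must propagate.

Potency across a cohort is also summarized by the normalized area under
the viability-vs-log10(dose) curve; AUC = 1 means no drug effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .errors import FitError, ValidationError

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "AUCResult",
    "FitOptions",
    "hill_viability",
    "invert_hill",
    "fit_hill",
    "compute_auc",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Paired (concentration, viability) observations for one drug on one
    cell line.  Concentrations are in uM and must be positive (the zero
    dose defines the normalization, not a curve point)."""

    drug: str
    cell_line: str
    points: tuple

    def __post_init__(self):
        pts = tuple((float(c), float(v)) for c, v in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ValidationError("a dose-response curve needs at least 2 points")
        if any(c <= 0 for c, _ in pts):
            raise ValidationError("concentrations must be > 0")
        if any(v < 0 or not np.isfinite(v) for _, v in pts):
            raise ValidationError("viabilities must be finite and >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def viabilities(self) -> np.ndarray:
        return np.array([v for _, v in self.points])

    @property
    def max_conc(self) -> float:
        return max(c for c, _ in self.points)

    @property
    def min_conc(self) -> float:
        return min(c for c, _ in self.points)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with censoring status.

    When ``censored`` is true the drug never reached 50% inhibition of
    the control within the tested range and ``ic50`` holds the lower
    bound max_conc rather than an estimate.
    """

    ic50: float
    hill_slope: float
    e0: float
    e_inf: float
    censored: bool
    max_conc: float
    loss: float
    converged: bool = True
    #: raw optimizer estimate, kept even when ic50 reports the censored bound
    ic50_fitted: Optional[float] = None

    def viability(self, conc) -> np.ndarray:
        return hill_viability(conc, self)


@dataclass(frozen=True)
class AUCResult:
    auc: float
    normalized: bool = True


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_hill`.

    The multi-start grid is deterministic, so ``seed`` only matters if
    ``extra_starts`` random restarts are requested.
    """

    max_iter: int = 5000
    tol: float = 1e-8
    seed: int = 0
    extra_starts: int = 0
    slope_bounds: Tuple[float, float] = (0.05, 10.0)
    e0_bounds: Tuple[float, float] = (0.5, 1.5)
    einf_bounds: Tuple[float, float] = (0.0, 1.0)


def hill_viability(conc, fit: HillFit):
    """Hill model viability at ``conc`` (scalar or array), in uM.

    At conc = 0 returns e0; at conc = ic50 returns (e0 + e_inf) / 2.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / fit.ic50) ** fit.hill_slope, 0.0)
    out = fit.e_inf + (fit.e0 - fit.e_inf) / (1.0 + ratio)
    return out.item() if np.isscalar(conc) else out


def invert_hill(fit: HillFit, viability_target: float) -> float:
    """Dose at which the fitted curve crosses ``viability_target``.

    Returns +inf when the target lies at or below the e_inf asymptote
    (never reached at any finite dose) and 0.0 when it lies at or above
    e0.
    """
    if viability_target >= fit.e0:
        return 0.0
    if viability_target <= fit.e_inf:
        return float("inf")
    ratio = (fit.e0 - viability_target) / (viability_target - fit.e_inf)
    return fit.ic50 * ratio ** (1.0 / fit.hill_slope)


def _hill_curve(theta, logc):
    log_ic50, log_slope, e0, e_inf = theta
    slope = np.exp(log_slope)
    # model in log10-dose: 1/(1+10^(slope*(logc - log_ic50)))
    z = slope * (logc - log_ic50) * np.log(10.0)
    z = np.clip(z, -500, 500)
    return e_inf + (e0 - e_inf) / (1.0 + np.exp(z))


def fit_hill(curve: DoseResponseCurve, opts: Optional[FitOptions] = None) -> HillFit:
    """Least-squares Hill fit with deterministic multi-start.

    Starts span a log-spaced IC50 grid over the tested range and slopes
    {0.5, 1, 2}; each start is refined with L-BFGS-B on (log10 IC50,
    log slope, e0, e_inf).  Censoring: if the fitted curve's minimum
    over [min dose, max dose] stays above 0.5 (i.e. the drug never
    inhibits 50% of the control), the fit is censored and ic50 is set to
    the bound max_conc.
    """
    opts = opts or FitOptions()
    if len(curve.points) < 4:
        raise FitError(f"need >= 4 points to fit, got {len(curve.points)}")
    logc = np.log10(curve.concentrations)
    v = curve.viabilities

    def objective(theta):
        resid = _hill_curve(theta, logc) - v
        return float(resid @ resid)

    lo_ic, hi_ic = logc.min() - 3.0, logc.max() + 3.0
    bounds = [
        (lo_ic, hi_ic),
        (np.log(opts.slope_bounds[0]), np.log(opts.slope_bounds[1])),
        opts.e0_bounds,
        opts.einf_bounds,
    ]
    e0_start = float(np.clip(v.max(initial=1.0), *opts.e0_bounds))
    einf_start = float(np.clip(v.min(), *opts.einf_bounds))
    ic_starts = np.linspace(logc.min(), logc.max(), 5)
    starts = [
        np.array([ic, np.log(s), e0_start, einf_start])
        for ic in ic_starts
        for s in (0.5, 1.0, 2.0)
    ]
    if opts.extra_starts:
        rng = np.random.default_rng(opts.seed)
        for _ in range(opts.extra_starts):
            starts.append(
                np.array(
                    [
                        rng.uniform(logc.min(), logc.max()),
                        rng.uniform(np.log(0.3), np.log(3.0)),
                        e0_start,
                        einf_start,
                    ]
                )
            )

    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.max_iter, "ftol": opts.tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    fit = HillFit(
        ic50=float(10.0 ** theta[0]),
        hill_slope=float(np.exp(theta[1])),
        e0=float(theta[2]),
        e_inf=float(theta[3]),
        censored=False,
        max_conc=curve.max_conc,
        loss=float(best.fun),
        converged=bool(best.success),
        ic50_fitted=float(10.0 ** theta[0]),
    )
    # Censoring is judged against the no-drug control (viability 1), not e0,
    # over the tested range only.
    grid = np.geomspace(curve.min_conc, curve.max_conc, 256)
    if float(np.min(hill_viability(grid, fit))) > 0.5:
        fit = replace(fit, censored=True, ic50=curve.max_conc)
    return fit


def compute_auc(curve: DoseResponseCurve) -> AUCResult:
    """Normalized AUC of viability over log10 concentration.

    The trapezoidal integral is divided by the log10 dose span so a
    no-effect curve (viability identically 1) scores exactly 1 whatever
    the dose range; complete kill scores 0.
    """
    if len(curve.points) < 2:
        raise FitError("AUC needs at least 2 points")
    order = np.argsort(curve.concentrations)
    logc = np.log10(curve.concentrations[order])
    v = curve.viabilities[order]
    span = logc[-1] - logc[0]
    if span <= 0:
        raise FitError("AUC needs at least 2 distinct concentrations")
    return AUCResult(auc=float(np.trapezoid(v, logc) / span), normalized=True)
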