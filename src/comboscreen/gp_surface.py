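"""Gaussian-process model of the combination dose-response surface.

Checkerboard combination screens measure viability on a small dose cross
(49 points for the 7x7 design).  Parametric response-surface models
(e.g. multidimensional logistic) are too rigid for the surfaces seen in
patient-derived lines, so the surface is modelled non-parametrically
with an exact Gaussian process: a squared-exponential kernel with one
length-scale per log-dose axis plus independent Gaussian noise, on
inputs log10(dose + zero_dose_offset).  With 49 observations exact
inference is cheap, so hyperparameters are chosen by maximizing the log
marginal likelihood with a gradient-based optimizer from a deterministic
grid of initializations (for an exact GP the evidence lower bound is
tight, so this is the same objective).

Predictions are confined to the measured dose box: the model is an
interpolator of the screen, and extrapolated synergy claims are refused
by construction.  Iso-effect contours (the dose pairs achieving a fixed
inhibition level on the posterior mean) are traced by bisection along
rays from the origin of the dose box; they are the substrate for the
Chou-Talalay combination-index analysis in :mod:`comboscreen.synergy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import DoseRangeError, FitError, ValidationError
from .plates import CombinationGrid

__all__ = [
    "GPFitOptions",
    "GPSurface",
    "IsoEffectContour",
    "fit_gp_surface",
    "predict_inhibition",
    "find_isoeffect",
]


@dataclass(frozen=True)
class GPFitOptions:
    """Hyperparameter-search settings.

    ``starts`` is a deterministic list of (signal_sd, length_scale,
    noise_sd) kernel initializations (length-scales in log10-dose units,
    shared across both axes at the start).  ``extra_restarts`` adds
    seeded random initializations on top.
    """

    starts: Tuple[Tuple[float, float, float], ...] = (
        (1.0, 1.0, 1e-2),
        (0.5, 0.5, 1e-3),
        (1.0, 2.0, 1e-4),
        (0.2, 1.0, 1e-2),
    )
    extra_restarts: int = 0
    seed: int = 0
    zero_dose_offset: Optional[float] = None  # default: min nonzero dose / 10
    signal_bounds: Tuple[float, float] = (1e-8, 1e3)
    length_bounds: Tuple[float, float] = (1e-2, 1e2)
    noise_bounds: Tuple[float, float] = (1e-12, 1.0)
    degenerate_signal_var: float = 1e-6


@dataclass
class GPSurface:
    """Fitted GP posterior over one combination grid."""

    grid: CombinationGrid
    kernel_params: dict
    log_evidence: float
    zero_dose_offset: float
    start_log_evidence: tuple
    degenerate: bool
    _gpr: GaussianProcessRegressor

    @property
    def max_dose_a(self) -> float:
        return float(self.grid.doses_a[-1])

    @property
    def max_dose_b(self) -> float:
        return float(self.grid.doses_b[-1])

    def _transform(self, conc_a, conc_b) -> np.ndarray:
        a = np.atleast_1d(np.asarray(conc_a, dtype=float))
        b = np.atleast_1d(np.asarray(conc_b, dtype=float))
        return np.column_stack(
            [np.log10(a + self.zero_dose_offset), np.log10(b + self.zero_dose_offset)]
        )

    def predict_viability(self, conc_a, conc_b, return_sd: bool = False):
        """Posterior mean viability (and predictive sd) at dose pairs.

        No range check here; use :func:`predict_inhibition` for the
        range-guarded public query.
        """
        X = self._transform(conc_a, conc_b)
        if return_sd:
            mean, sd = self._gpr.predict(X, return_std=True)
            if np.isscalar(conc_a) and np.isscalar(conc_b):
                return float(mean[0]), float(sd[0])
            return mean, sd
        mean = self._gpr.predict(X)
        if np.isscalar(conc_a) and np.isscalar(conc_b):
            return float(mean[0])
        return mean


@dataclass(frozen=True)
class IsoEffectContour:
    """Dose pairs on the posterior mean achieving a fixed inhibition level.

    ``reached`` is false (and ``points`` empty) when the surface's
    maximum inhibition over the measured range falls short of the level;
    downstream CI calculations must then report no values.
    """

    effect_level: float
    points: tuple
    reached: bool


def _grid_xy(grid: CombinationGrid, offset: float):
    A, B = np.meshgrid(grid.doses_a, grid.doses_b, indexing="ij")
    X = np.column_stack(
        [np.log10(A.ravel() + offset), np.log10(B.ravel() + offset)]
    )
    return X, grid.viabilities.ravel()


def fit_gp_surface(
    grid: CombinationGrid, opts: Optional[GPFitOptions] = None
) -> GPSurface:
    """Fit the GP surface, maximizing the exact log marginal likelihood.

    Each deterministic start is refined with L-BFGS; the restart with the
    highest evidence wins, and the recorded per-start evidences allow a
    no-regression check (final evidence >= every start's initial value).
    A constant grid fits successfully but is flagged ``degenerate`` via a
    near-zero signal variance.
    """
    opts = opts or GPFitOptions()
    offset = opts.zero_dose_offset
    if offset is None:
        nonzero = np.concatenate(
            [grid.doses_a[grid.doses_a > 0], grid.doses_b[grid.doses_b > 0]]
        )
        if len(nonzero) == 0:
            raise FitError("grid has no nonzero doses")
        offset = float(nonzero.min() / 10.0)
    X, y = _grid_xy(grid, offset)

    starts = [tuple(s) for s in opts.starts]
    if opts.extra_restarts:
        rng = np.random.default_rng(opts.seed)
        for _ in range(opts.extra_restarts):
            starts.append(
                (
                    float(rng.uniform(0.1, 2.0)),
                    float(rng.uniform(0.3, 3.0)),
                    float(10.0 ** rng.uniform(-4, -1)),
                )
            )

    best = None
    start_lls: List[float] = []
    for signal_sd, ls, noise_sd in starts:
        kernel = ConstantKernel(
            signal_sd**2, constant_value_bounds=opts.signal_bounds
        ) * RBF([ls, ls], length_scale_bounds=opts.length_bounds) + WhiteKernel(
            noise_sd**2, noise_level_bounds=opts.noise_bounds
        )
        gpr = GaussianProcessRegressor(
            kernel=kernel,
            optimizer="fmin_l_bfgs_b",
            n_restarts_optimizer=0,
            normalize_y=True,
            random_state=0,
        )
        with warnings.catch_warnings():
            # individual starts may stall at a hyperparameter bound; only
            # the best restart matters
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(X, y)
        start_lls.append(float(gpr.log_marginal_likelihood(np.log([signal_sd**2, ls, ls, noise_sd**2]))))
        ll = float(gpr.log_marginal_likelihood_value_)
        if best is None or ll > best[0]:
            best = (ll, gpr)

    ll, gpr = best
    k = gpr.kernel_
    params = {
        "signal_variance": float(k.k1.k1.constant_value),
        "length_scales": tuple(float(v) for v in np.atleast_1d(k.k1.k2.length_scale)),
        "noise_variance": float(k.k2.noise_level),
    }
    return GPSurface(
        grid=grid,
        kernel_params=params,
        log_evidence=ll,
        zero_dose_offset=offset,
        start_log_evidence=tuple(start_lls),
        degenerate=params["signal_variance"] < opts.degenerate_signal_var,
        _gpr=gpr,
    )


def predict_inhibition(surface: GPSurface, conc_a: float, conc_b: float):
    """(mean inhibition, posterior sd) at one dose pair.

    Inhibition = 1 - posterior mean viability.  Queries outside the
    measured dose box raise :class:`DoseRangeError`: the screen only
    supports claims within its measured range.
    """
    if not (0 <= conc_a <= surface.max_dose_a and 0 <= conc_b <= surface.max_dose_b):
        raise DoseRangeError(
            f"query ({conc_a}, {conc_b}) uM outside the measured dose box "
            f"[0, {surface.max_dose_a}] x [0, {surface.max_dose_b}]"
        )
    mean, sd = surface.predict_viability(conc_a, conc_b, return_sd=True)
    return 1.0 - mean, sd


def _max_inhibition(surface: GPSurface, n: int = 41) -> float:
    # dense evaluation over the measured box, log-spaced from the offset
    off = surface.zero_dose_offset
    ga = np.concatenate([[0.0], np.geomspace(off, surface.max_dose_a, n - 1)])
    gb = np.concatenate([[0.0], np.geomspace(off, surface.max_dose_b, n - 1)])
    A, B = np.meshgrid(ga, gb, indexing="ij")
    v = surface.predict_viability(A.ravel(), B.ravel())
    return float(np.max(1.0 - v))


def find_isoeffect(
    surface: GPSurface,
    effect_level: float,
    n_rays: int = 50,
    tol: float = 1e-3,
    max_bisect: int = 80,
) -> IsoEffectContour:
    """Trace the iso-effect contour at ``effect_level`` on the posterior mean.

    Rays run from the origin of the dose box to points spread along its
    far edges; along each ray the first crossing of the target
    inhibition is located by a coarse scan plus bisection (tolerance
    ``tol`` in inhibition).  When the surface's maximum inhibition over
    the measured range is below the level, the contour is reported as
    not reached with no points.
    """
    if not (0 < effect_level < 1):
        raise ValidationError(f"effect_level must be in (0, 1), got {effect_level}")
    if _max_inhibition(surface) < effect_level:
        return IsoEffectContour(effect_level=effect_level, points=(), reached=False)

    amax, bmax = surface.max_dose_a, surface.max_dose_b
    n_half = max(2, n_rays // 2)
    endpoints = [(amax, f * bmax) for f in np.linspace(0, 1, n_half)]
    endpoints += [(f * amax, bmax) for f in np.linspace(0, 1, n_half)[:-1]]

    points = []
    for ea, eb in endpoints:
        def inhib(t: float) -> float:
            v = surface.predict_viability(t * ea, t * eb)
            return 1.0 - v

        # coarse scan for the first upward crossing
        ts = np.linspace(0.0, 1.0, 33)
        vals = [inhib(t) for t in ts]
        bracket = None
        for (t0, f0), (t1, f1) in zip(zip(ts, vals), zip(ts[1:], vals[1:])):
            if f0 < effect_level <= f1:
                bracket = (t0, t1)
                break
        if bracket is None:
            continue
        lo, hi = bracket
        for _ in range(max_bisect):
            mid = 0.5 * (lo + hi)
            f = inhib(mid)
            if abs(f - effect_level) < tol:
                lo = hi = mid
                break
            if f < effect_level:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        points.append((t * ea, t * eb))

    return IsoEffectContour(
        effect_level=effect_level, points=tuple(points), reached=len(points) > 0
    )
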