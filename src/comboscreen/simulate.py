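"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here under a single
seeded RNG (numpy PCG64), with the planted truth returned alongside the
data so pipeline-versus-truth comparisons are mechanical:

* single-agent plates — Hill-shaped viability on a geometric dilution
  series (default: the screen's 13 three-fold dilutions from 10 uM),
  additive Gaussian noise truncated at 0, raw signals rescaled to a
  control level with replicate control wells;
* combination grids — 7x7 dose crosses (zero row/column embedded)
  generated exactly under Bliss independence, exactly under Loewe
  additivity (per-cell bisection on the effect level), or with a
  controlled synergy multiplier on the Bliss-expected inhibition;
* RPPA matrices — normal log2 affinities with a planted set of
  differential antibodies in designated strata of a drug-vs-vehicle,
  two-timepoint, two-sensitivity-class design;
* tumor-growth cohorts — exponential growth from a common baseline with
  a multiplicative treatment effect after the treatment-start day,
  emitted as caliper (length, width) pairs with W = 0.8 L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dose_response import HillFit
from .errors import GeneratorError, ValidationError
from .pdx import TumorMeasurement
from .plates import CombinationGrid, DoseSeries, Well, build_single_agent_series
from .rppa import RPPAMatrix

__all__ = [
    "HillParams",
    "GeneratorSpec",
    "default_single_agent_series",
    "default_combination_axes",
    "gen_single_agent_plate",
    "gen_combination_grid",
    "gen_rppa_matrix",
    "gen_growth_curves",
]


@dataclass(frozen=True)
class HillParams:
    """True Hill parameters of one simulated drug."""

    ic50: float
    slope: float
    e0: float = 1.0
    e_inf: float = 0.0

    def viability(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, (c / self.ic50) ** self.slope, 0.0)
        return self.e_inf + (self.e0 - self.e_inf) / (1.0 + ratio)

    def inverse(self, viability: float) -> float:
        """Dose giving the target viability (inf if below e_inf)."""
        if viability >= self.e0:
            return 0.0
        if viability <= self.e_inf:
            return float("inf")
        ratio = (self.e0 - viability) / (viability - self.e_inf)
        return self.ic50 * ratio ** (1.0 / self.slope)

    def as_fit(self, max_conc: float, censored: bool = False) -> HillFit:
        return HillFit(
            ic50=max_conc if censored else self.ic50,
            hill_slope=self.slope,
            e0=self.e0,
            e_inf=self.e_inf,
            censored=censored,
            max_conc=max_conc,
            loss=0.0,
        )


@dataclass(frozen=True)
class RPPASpec:
    n_antibodies: int = 1000
    n_planted: int = 50
    effect_size: float = 1.0  # log2 shift in the drug arm
    noise_sd: float = 0.25
    n_per_arm: int = 3


@dataclass(frozen=True)
class GrowthSpec:
    baseline_volume: float = 350.0  # mm^3 at enrollment
    growth_rate: float = 0.0145  # per day (vehicle doubles roughly every 7 weeks)
    treatment_multiplier: float = 0.27  # endpoint volume ratio, treated / vehicle
    treatment_start_day: int = 0
    n_days: int = 28
    noise_sd: float = 0.1  # lognormal sd on volumes (typical caliper variability)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for all generators; the seed fully determines output."""

    seed: int = 0
    noise_sd: float = 0.05
    hill_params: Mapping[str, HillParams] = field(
        default_factory=lambda: {
            "drug_a": HillParams(ic50=0.1, slope=1.0),
            "drug_b": HillParams(ic50=0.5, slope=1.0),
        }
    )
    surface_mode: str = "bliss"  # bliss | loewe | synergy | antagonism
    synergy_strength: float = 0.0
    rppa: RPPASpec = field(default_factory=RPPASpec)
    growth: GrowthSpec = field(default_factory=GrowthSpec)

    def __post_init__(self):
        if self.surface_mode not in ("bliss", "loewe", "synergy", "antagonism"):
            raise ValidationError(f"unknown surface_mode {self.surface_mode!r}")
        if self.synergy_strength < -1:
            raise ValidationError("synergy_strength must be >= -1")


def default_single_agent_series(drug: str = "trametinib") -> DoseSeries:
    """The screen's single-agent design: 13 three-fold dilutions from 10 uM."""
    return build_single_agent_series(10.0, 13, 3.0, drug=drug)


def default_combination_axes(
    drug_a: str = "trametinib", drug_b: str = "partner"
) -> Tuple[DoseSeries, DoseSeries]:
    """Combination-axis designs: trametinib from 0.03 uM, partner from 1 uM,
    six three-fold dilution steps each (plus the zero dose added at grid
    assembly)."""
    return (
        build_single_agent_series(0.03, 6, 3.0, drug=drug_a),
        build_single_agent_series(1.0, 6, 3.0, drug=drug_b),
    )


def _noisy_viability(v: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    if noise_sd == 0:
        return np.array(v, dtype=float)
    return np.maximum(0.0, v + rng.normal(0.0, noise_sd, size=np.shape(v)))


def gen_single_agent_plate(
    spec: GeneratorSpec,
    series: Optional[DoseSeries] = None,
    drug: str = "drug_a",
    n_controls: int = 8,
    control_scale: float = 1.0,
):
    """Simulate one single-agent plate: (wells, truth).

    Viabilities come from the drug's true Hill model at the series doses
    plus truncated Gaussian noise, then are converted to raw signals by
    the control scale; ``n_controls`` no-drug wells carry the same noise.
    Truth holds the :class:`HillParams` and the noise-free viabilities.
    """
    series = series or default_single_agent_series(drug)
    params = spec.hill_params[drug]
    rng = np.random.default_rng(spec.seed)
    concs = np.array(series.concentrations)
    clean = params.viability(concs)
    noisy = _noisy_viability(clean, spec.noise_sd, rng)
    control_noise = _noisy_viability(np.ones(n_controls), spec.noise_sd, rng)
    wells = [
        Well(
            row="A",
            col=i + 1,
            drug_a=series.drug,
            conc_a=float(c),
            drug_b=None,
            conc_b=0.0,
            raw_signal=float(v * control_scale),
            is_control=False,
        )
        for i, (c, v) in enumerate(zip(concs, noisy))
    ]
    wells += [
        Well(
            row="H",
            col=i + 1,
            drug_a=None,
            conc_a=0.0,
            drug_b=None,
            conc_b=0.0,
            raw_signal=float(v * control_scale),
            is_control=True,
        )
        for i, v in enumerate(control_noise)
    ]
    truth = {
        "drug": series.drug,
        "hill": params,
        "viability_clean": clean,
        "series": series,
    }
    return wells, truth


def _loewe_viability(da: float, db: float, pa: HillParams, pb: HillParams) -> float:
    """Solve d_A/D_A(E) + d_B/D_B(E) = 1 for the Loewe-additive effect E.

    D_X(E) is the single-agent dose of X producing inhibition E.  The
    left side decreases monotonically in E from +inf to 0, so bisection
    always converges for margins with e0 = 1 and e_inf = 0.
    """
    if da == 0 and db == 0:
        return 1.0
    if pa.e_inf > 0 or pb.e_inf > 0 or pa.e0 != 1 or pb.e0 != 1:
        raise GeneratorError(
            "Loewe generation requires margins with e0 = 1 and e_inf = 0"
        )

    def excess(effect: float) -> float:
        total = 0.0
        if da > 0:
            total += da / pa.inverse(1.0 - effect)
        if db > 0:
            total += db / pb.inverse(1.0 - effect)
        return total - 1.0

    lo, hi = 1e-12, 1.0 - 1e-12
    if excess(lo) < 0:
        return 1.0  # doses too small to register any effect
    f_lo = excess(lo)
    f_hi = excess(hi)
    if f_lo * f_hi > 0:
        raise GeneratorError("Loewe bisection failed to bracket the effect level")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = excess(mid)
        if abs(f) < 1e-8:
            return 1.0 - mid
        if f > 0:
            lo = mid
        else:
            hi = mid
    if hi - lo > 1e-6:
        raise GeneratorError("Loewe bisection did not converge")
    return 1.0 - 0.5 * (lo + hi)


def gen_combination_grid(
    spec: GeneratorSpec,
    axes: Optional[Tuple[DoseSeries, DoseSeries]] = None,
    drugs: Tuple[str, str] = ("drug_a", "drug_b"),
    grid_axes: str = "with_zero",
):
    """Simulate one combination grid: (CombinationGrid, truth).

    ``surface_mode`` selects the generating law on the noise-free scale:

    * ``bliss``    — viability(i, j) = v_A(i) * v_B(j);
    * ``loewe``    — effect solves the Loewe iso-bole equation by
      bisection per cell;
    * ``synergy`` / ``antagonism`` — inhibition = min(1, (1 + s) * Bliss
      inhibition) with s = ``synergy_strength`` (negative for
      antagonism).

    Gaussian noise (sd ``noise_sd``, truncated at 0) is added last.  The
    default ``with_zero`` layout prepends the zero dose to each axis so
    single-agent margins are embedded (7x7 with the default 6-step
    axes); ``all_nonzero`` keeps only treated doses.
    """
    axes = axes or default_combination_axes(*drugs)
    series_a, series_b = axes
    pa = spec.hill_params[drugs[0]]
    pb = spec.hill_params[drugs[1]]
    rng = np.random.default_rng(spec.seed)

    da = np.sort(np.array(series_a.concentrations))
    db = np.sort(np.array(series_b.concentrations))
    if grid_axes == "with_zero":
        da = np.concatenate([[0.0], da])
        db = np.concatenate([[0.0], db])
    elif grid_axes != "all_nonzero":
        raise ValidationError(f"grid_axes must be 'with_zero' or 'all_nonzero'")

    va = pa.viability(da)
    vb = pb.viability(db)
    if spec.surface_mode == "loewe":
        clean = np.array(
            [[_loewe_viability(x, y, pa, pb) for y in db] for x in da]
        )
    else:
        bliss = np.outer(va, vb)
        if spec.surface_mode == "bliss":
            clean = bliss
        else:
            # the interaction multiplier touches only true combination cells;
            # single-agent margins keep their Hill-model values
            s = spec.synergy_strength
            inhibition = np.minimum(1.0, (1.0 + s) * (1.0 - bliss))
            combo = np.outer(da > 0, db > 0)
            clean = np.where(combo, 1.0 - inhibition, bliss)
    noisy = _noisy_viability(clean, spec.noise_sd, rng)
    if grid_axes == "with_zero":
        noisy[0, 0] = 1.0  # anchor of the normalization
    grid = CombinationGrid(
        drug_a=series_a.drug,
        drug_b=series_b.drug,
        doses_a=da,
        doses_b=db,
        viabilities=noisy,
    )
    truth = {
        "mode": spec.surface_mode,
        "synergy_strength": spec.synergy_strength,
        "hill_a": pa,
        "hill_b": pb,
        "viability_clean": clean,
    }
    return grid, truth


def gen_rppa_matrix(
    spec: GeneratorSpec,
    planted_strata: Optional[Sequence[Mapping[str, str]]] = None,
    n_caution: int = 0,
):
    """Simulate an RPPA experiment: (RPPAMatrix, truth).

    The design crosses sensitivity class (sensitive/resistant),
    treatment (drug/vehicle) and timepoint (24h/72h) with ``n_per_arm``
    cell-line replicates per cell of the design.  The first
    ``n_planted`` antibodies are shifted by ``effect_size`` in the drug
    arm of the ``planted_strata`` (default: every stratum).
    ``n_caution`` extra antibodies carry 'caution' validation status to
    exercise the validated-only filter.
    """
    r = spec.rppa
    if r.n_planted > r.n_antibodies:
        raise ValidationError("n_planted cannot exceed n_antibodies")
    rng = np.random.default_rng(spec.seed)
    antibodies = [f"ab{i:04d}" for i in range(r.n_antibodies + n_caution)]
    status = ["validated"] * r.n_antibodies + ["caution"] * n_caution
    planted = antibodies[: r.n_planted]

    samples, meta_rows = [], []
    for sens in ("sensitive", "resistant"):
        for tp in ("24h", "72h"):
            for trt in ("drug", "vehicle"):
                for k in range(r.n_per_arm):
                    sid = f"{sens[:3]}_{tp}_{trt}_{k}"
                    samples.append(sid)
                    meta_rows.append(
                        {
                            "sample": sid,
                            "cell_line": f"line_{sens[:3]}_{k}",
                            "sensitivity": sens,
                            "treatment": trt,
                            "timepoint": tp,
                        }
                    )
    meta = pd.DataFrame(meta_rows).set_index("sample")

    baseline = rng.normal(0.0, 1.0, size=len(antibodies))
    values = rng.normal(0.0, r.noise_sd, size=(len(antibodies), len(samples)))
    values += baseline[:, None]

    def in_planted_stratum(row) -> bool:
        if row["treatment"] != "drug":
            return False
        if planted_strata is None:
            return True
        return any(
            all(row[k] == v for k, v in stratum.items()) for stratum in planted_strata
        )

    shifted_cols = [
        j for j, (_, row) in enumerate(meta.iterrows()) if in_planted_stratum(row)
    ]
    values[: r.n_planted, shifted_cols] += r.effect_size

    matrix = RPPAMatrix(
        values=pd.DataFrame(values, index=antibodies, columns=samples),
        antibody_meta=pd.DataFrame({"status": status}, index=antibodies),
        sample_meta=meta,
    )
    truth = {
        "planted": planted,
        "effect_size": r.effect_size,
        "planted_strata": planted_strata,
    }
    return matrix, truth


def gen_growth_curves(
    spec: GeneratorSpec,
    groups: Optional[Mapping[str, int]] = None,
):
    """Simulate a xenograft cohort: (list of TumorMeasurement, truth).

    Vehicle tumors grow exponentially from the common baseline; treated
    tumors are scaled by ``treatment_multiplier`` after the
    treatment-start day, so on noise-free curves the endpoint percent
    reduction is exactly 100 * (1 - multiplier).  Volumes become
    caliper pairs via W = 0.8 L and V = L W^2 / 2.
    """
    g = spec.growth
    groups = groups or {"vehicle": 8, "treatment": 6}
    rng = np.random.default_rng(spec.seed)
    measurements: List[TumorMeasurement] = []
    truth_volumes: Dict[str, np.ndarray] = {}
    days = np.arange(0, g.n_days + 1)
    for group, n in groups.items():
        base = g.baseline_volume * np.exp(g.growth_rate * days)
        if group != "vehicle":
            mult = np.where(days > g.treatment_start_day, g.treatment_multiplier, 1.0)
            base = base * mult
        truth_volumes[group] = base
        for i in range(n):
            vols = base.copy()
            if g.noise_sd > 0:
                vols = vols * np.exp(rng.normal(0.0, g.noise_sd, size=len(days)))
            # V = L * (0.8 L)^2 / 2 = 0.32 L^3
            lengths = (vols / 0.32) ** (1.0 / 3.0)
            widths = 0.8 * lengths
            for d, L, W in zip(days, lengths, widths):
                measurements.append(
                    TumorMeasurement(
                        animal_id=f"{group}_{i}",
                        day=int(d),
                        length=float(L),
                        width=float(W),
                        group=group,
                    )
                )
    truth = {"volumes_by_group": truth_volumes, "spec": g}
    return measurements, truth
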