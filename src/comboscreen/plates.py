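"""Plate-level data model for viability screens.

A screen is a collection of wells, each carrying up to two drugs at known
concentrations plus a raw absorbance signal from a metabolic (MTS-type)
readout.  Raw signals are normalized to the mean of the no-drug control
wells, giving viability fractions on which all downstream dose-response
and synergy analysis operates.  Single-agent experiments use geometric
dilution series (e.g. 13 three-fold dilutions from 10 uM); combinations
use a full dose cross ("checkerboard"), by default a 7x7 grid whose first
row and column are the zero doses, so that single-agent margins are
embedded in the grid.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    GridAssemblyError,
    NormalizationError,
    PlateFormatError,
    ValidationError,
)

__all__ = [
    "Well",
    "DoseSeries",
    "CombinationGrid",
    "read_plate",
    "write_plate",
    "normalize_to_control",
    "build_single_agent_series",
    "assemble_combination_grid",
    "load_layout",
    "DEFAULT_LAYOUT",
]

#: Default mapping from logical field -> CSV column name.
DEFAULT_LAYOUT: Mapping[str, str] = {
    "plate_id": "plate_id",
    "well": "well",
    "drug_a": "drug_a",
    "conc_a": "conc_a_uM",
    "drug_b": "drug_b",
    "conc_b": "conc_b_uM",
    "signal": "signal",
}

_WELL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def load_layout(path) -> dict:
    """Load a plate layout config (logical field -> column name) from YAML."""
    with open(path) as fh:
        layout = yaml.safe_load(fh)
    if not isinstance(layout, dict):
        raise PlateFormatError(f"layout config {path} must be a mapping")
    unknown = set(layout) - set(DEFAULT_LAYOUT)
    if unknown:
        raise PlateFormatError(f"unknown layout fields: {sorted(unknown)}")
    return layout


@dataclass(frozen=True)
class Well:
    """One plate well.

    ``is_control`` is true exactly when both concentrations are zero
    (a no-drug well used for normalization).
    """

    row: str
    col: int
    drug_a: Optional[str]
    conc_a: float
    drug_b: Optional[str]
    conc_b: float
    raw_signal: float
    is_control: bool = False

    def __post_init__(self):
        for name, c in (("conc_a", self.conc_a), ("conc_b", self.conc_b)):
            if not math.isfinite(c) or c < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {c}")
        if not math.isfinite(self.raw_signal) or self.raw_signal < 0:
            raise ValidationError(f"raw_signal must be finite and >= 0, got {self.raw_signal}")
        expected_control = self.conc_a == 0 and self.conc_b == 0
        if self.is_control != expected_control:
            raise ValidationError(
                "is_control must hold exactly when both concentrations are zero "
                f"(conc_a={self.conc_a}, conc_b={self.conc_b}, is_control={self.is_control})"
            )


@dataclass(frozen=True)
class DoseSeries:
    """Geometric dilution series for one drug: strictly decreasing doses
    with a constant dilution factor between consecutive points."""

    drug: str
    concentrations: tuple
    dilution_factor: float

    def __post_init__(self):
        concs = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", concs)
        if len(concs) < 2:
            raise ValidationError("a dose series needs at least 2 points")
        if any(c <= 0 for c in concs):
            raise ValidationError("dose-series concentrations must be positive")
        for hi, lo in zip(concs, concs[1:]):
            if not hi > lo:
                raise ValidationError("concentrations must be strictly decreasing")
            if abs(hi / lo - self.dilution_factor) > 1e-9 * self.dilution_factor:
                raise ValidationError(
                    f"consecutive ratio {hi / lo} != dilution_factor {self.dilution_factor}"
                )

    @property
    def n_points(self) -> int:
        return len(self.concentrations)

    @property
    def top_conc(self) -> float:
        return self.concentrations[0]


def build_single_agent_series(
    top_conc: float, n_points: int, dilution: float, drug: str = "drug"
) -> DoseSeries:
    """Build the geometric series conc[i] = top_conc / dilution**i.

    The standard single-agent design is 13 three-fold dilutions from
    10 uM; the combination axes use 6 three-fold dilutions from the
    drug-specific top dose.
    """
    if top_conc <= 0:
        raise ValidationError(f"top_conc must be > 0, got {top_conc}")
    if n_points < 2:
        raise ValidationError(f"n_points must be >= 2, got {n_points}")
    if dilution <= 1:
        raise ValidationError(f"dilution must be > 1, got {dilution}")
    concs = tuple(top_conc / dilution**i for i in range(n_points))
    return DoseSeries(drug=drug, concentrations=concs, dilution_factor=float(dilution))


@dataclass
class CombinationGrid:
    """Dose cross of two drugs with normalized viability at each dose pair.

    ``doses_a`` (rows) and ``doses_b`` (columns) are ascending and, in the
    default ``with_zero`` layout, start at 0 so the first row/column hold
    the embedded single-agent responses and ``viabilities[0, 0] == 1`` by
    construction after normalization.  Viabilities above 1 (drug-induced
    stimulation of metabolic rate, observed in some resistant lines) are
    retained, capped at ``cap``.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viabilities: np.ndarray
    cap: float = 2.0

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viabilities = np.asarray(self.viabilities, dtype=float)
        if self.doses_a.ndim != 1 or self.doses_b.ndim != 1:
            raise ValidationError("dose axes must be 1-D")
        if len(self.doses_a) < 2 or len(self.doses_b) < 2:
            raise ValidationError("each dose axis needs at least 2 doses")
        if np.any(self.doses_a < 0) or np.any(self.doses_b < 0):
            raise ValidationError("doses must be non-negative")
        if np.any(np.diff(self.doses_a) <= 0) or np.any(np.diff(self.doses_b) <= 0):
            raise ValidationError("dose axes must be strictly increasing")
        if self.viabilities.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValidationError(
                f"viability matrix shape {self.viabilities.shape} does not match axes "
                f"({len(self.doses_a)}, {len(self.doses_b)})"
            )
        if np.any(~np.isfinite(self.viabilities)) or np.any(self.viabilities < 0):
            raise ValidationError("viabilities must be finite and >= 0")
        if np.any(self.viabilities > self.cap):
            warnings.warn(
                f"viabilities above cap {self.cap} were clipped", stacklevel=2
            )
            self.viabilities = np.minimum(self.viabilities, self.cap)

    @property
    def has_zero_doses(self) -> bool:
        return self.doses_a[0] == 0 and self.doses_b[0] == 0

    def single_agent_margin(self, which: str) -> np.ndarray:
        """Embedded single-agent viabilities along one axis ('a' or 'b')."""
        if not self.has_zero_doses:
            raise ValidationError("grid has no zero-dose row/column; margins not embedded")
        if which == "a":
            return self.viabilities[:, 0]
        if which == "b":
            return self.viabilities[0, :]
        raise ValidationError(f"which must be 'a' or 'b', got {which!r}")

    def transpose(self) -> "CombinationGrid":
        return CombinationGrid(
            drug_a=self.drug_b,
            drug_b=self.drug_a,
            doses_a=self.doses_b.copy(),
            doses_b=self.doses_a.copy(),
            viabilities=self.viabilities.T.copy(),
            cap=self.cap,
        )

    def to_frame(self) -> pd.DataFrame:
        """Grid as a DataFrame with dose-labelled index/columns (for CSV export)."""
        return pd.DataFrame(self.viabilities, index=self.doses_a, columns=self.doses_b)


def _parse_well_label(label: str):
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise PlateFormatError(f"unparseable well label {label!r}")
    return m.group(1).upper(), int(m.group(2))


def read_plate(path, layout_config: Optional[Mapping[str, str]] = None) -> list:
    """Read a plate CSV into a list of :class:`Well`.

    ``layout_config`` maps logical fields to CSV column names (defaults in
    :data:`DEFAULT_LAYOUT`).  Unknown drug names are preserved verbatim;
    empty drug cells with zero concentration denote untreated axes.
    """
    layout = dict(DEFAULT_LAYOUT)
    if layout_config:
        layout.update(layout_config)
    df = pd.read_csv(path)
    required = [layout[k] for k in ("well", "conc_a", "conc_b", "signal")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateFormatError(f"plate file {path} lacks required columns: {missing}")
    wells = []
    for _, rec in df.iterrows():
        row, col = _parse_well_label(rec[layout["well"]])
        conc_a = float(rec[layout["conc_a"]])
        conc_b = float(rec[layout["conc_b"]])
        if conc_a < 0 or conc_b < 0:
            raise ValidationError(
                f"negative concentration in well {rec[layout['well']]}"
            )

        def _drug(key):
            colname = layout[key]
            if colname not in df.columns:
                return None
            v = rec[colname]
            if pd.isna(v) or str(v).strip() == "":
                return None
            return str(v)

        wells.append(
            Well(
                row=row,
                col=col,
                drug_a=_drug("drug_a"),
                conc_a=conc_a,
                drug_b=_drug("drug_b"),
                conc_b=conc_b,
                raw_signal=float(rec[layout["signal"]]),
                is_control=(conc_a == 0 and conc_b == 0),
            )
        )
    return wells


def write_plate(wells: Iterable[Well], path, plate_id: str = "plate1") -> None:
    """Write wells back to the canonical plate CSV layout."""
    rows = [
        {
            "plate_id": plate_id,
            "well": f"{w.row}{w.col}",
            "drug_a": "" if w.drug_a is None else w.drug_a,
            "conc_a_uM": w.conc_a,
            "drug_b": "" if w.drug_b is None else w.drug_b,
            "conc_b_uM": w.conc_b,
            "signal": w.raw_signal,
        }
        for w in wells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def normalize_to_control(wells: Sequence[Well]) -> dict:
    """Normalize raw signals to the mean signal of the no-drug control wells.

    Returns a mapping well -> viability fraction; the control mean maps to
    exactly 1.  Multiplying every raw signal by a constant leaves the
    result unchanged.
    """
    controls = [w for w in wells if w.is_control]
    if not controls:
        raise NormalizationError("no control (no-drug) wells present")
    control_mean = float(np.mean([w.raw_signal for w in controls]))
    if control_mean <= 0:
        raise NormalizationError(f"control mean signal must be > 0, got {control_mean}")
    return {w: w.raw_signal / control_mean for w in wells}


def _doses_in_well(well: Well, drug: str) -> float:
    dose = 0.0
    if well.drug_a == drug:
        dose += well.conc_a
    if well.drug_b == drug:
        dose += well.conc_b
    return dose


def assemble_combination_grid(
    wells: Sequence[Well],
    drug_a: str,
    drug_b: str,
    viabilities: Optional[Mapping[Well, float]] = None,
    cap: float = 2.0,
) -> CombinationGrid:
    """Assemble the dose cross of two drugs from normalized wells.

    Wells must cover the full cartesian product of the dose axes observed
    for the pair (including zero doses for the embedded single-agent
    margins and the control well at (0, 0)).  Replicate wells at the same
    dose pair are averaged with the arithmetic mean.  If ``viabilities``
    is not given, wells are normalized to controls here.
    """
    relevant = [
        w
        for w in wells
        if {d for d in (w.drug_a, w.drug_b) if d is not None} <= {drug_a, drug_b}
    ]
    if not relevant:
        raise GridAssemblyError(f"no wells involve only {drug_a!r}/{drug_b!r}")
    if viabilities is None:
        viabilities = normalize_to_control(relevant)

    by_pair: dict = {}
    for w in relevant:
        key = (_doses_in_well(w, drug_a), _doses_in_well(w, drug_b))
        by_pair.setdefault(key, []).append(viabilities[w])

    doses_a = np.array(sorted({k[0] for k in by_pair}))
    doses_b = np.array(sorted({k[1] for k in by_pair}))
    missing = [
        (da, db) for da in doses_a for db in doses_b if (da, db) not in by_pair
    ]
    if missing:
        raise GridAssemblyError(
            f"incomplete {len(doses_a)}x{len(doses_b)} grid for "
            f"({drug_a}, {drug_b}); missing dose pairs: {missing}",
            missing_pairs=missing,
        )
    mat = np.array(
        [[float(np.mean(by_pair[(da, db)])) for db in doses_b] for da in doses_a]
    )
    return CombinationGrid(
        drug_a=drug_a, drug_b=drug_b, doses_a=doses_a, doses_b=doses_b,
        viabilities=mat, cap=cap,
    )
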