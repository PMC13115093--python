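"""CSV and configuration I/O for every table the pipeline consumes.

Five schemas are defined (all comma-separated, UTF-8, ``.`` decimal mark,
required header, scientific notation accepted):

======================  =====================================================
file                    columns
======================  =====================================================
``conditions.csv``      mwco_kda, time_min, force_g, z_ave_nm,
                        count_rate_kcps, pdi, zeta_mv, conductivity
``titration.csv``       q_mol_per_l, intensity
``energy_frames.csv``   frame, vdw, ele, gb, surf [, internal]
``sweep.csv``           x, z_ave_nm [, count_rate_kcps]
``composition.csv``     component, group, mean, sd, n
======================  =====================================================

Reads are all-or-nothing: a malformed file raises before any record is
returned.  The run configuration is a JSON object; missing keys fall back
to the study defaults (five criteria weighted 0.15/0.20/0.25/0.15/0.25 with
Z-average, PDI and conductivity treated as cost criteria).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from teacolloid.errors import ParseError, SchemaError, ValidationError

#: Criterion order used throughout the TOPSIS stage.
CRITERIA: tuple[str, ...] = ("z_ave", "count_rate", "pdi", "zeta_abs", "conductivity")

#: Expert-consultation weights for the five colloidal criteria.
DEFAULT_WEIGHTS: tuple[float, ...] = (0.15, 0.20, 0.25, 0.15, 0.25)

#: Lower Z-average, PDI and conductivity are favourable (cost criteria);
#: higher count rate and |zeta| are favourable (benefit criteria).
DEFAULT_DIRECTIONS: tuple[str, ...] = ("cost", "benefit", "cost", "benefit", "cost")

_CONDITION_COLUMNS = (
    "mwco_kda",
    "time_min",
    "force_g",
    "z_ave_nm",
    "count_rate_kcps",
    "pdi",
    "zeta_mv",
    "conductivity",
)


@dataclass(frozen=True)
class ConditionRecord:
    """One ultrafiltration–centrifugation condition with its DLS readout.

    ``mwco_kda`` is the membrane molecular-weight cut-off (kDa),
    ``force_g`` the relative centrifugal force (×g), ``time_min`` the spin
    time.  Measured criteria: Z-average hydrodynamic diameter (nm), photon
    count rate (kcps), polydispersity index (dimensionless, in [0, 1]),
    zeta potential (mV, sign retained) and conductivity (instrument units,
    treated as opaque but positive).
    """

    mwco_kda: float
    time_min: float
    force_g: float
    z_ave_nm: float
    count_rate_kcps: float
    pdi: float
    zeta_mv: float
    conductivity: float

    def __post_init__(self) -> None:
        for name in ("mwco_kda", "time_min", "force_g", "z_ave_nm",
                     "count_rate_kcps", "conductivity"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if not (0.0 <= self.pdi <= 1.0):
            raise ValidationError(f"pdi must lie in [0, 1], got {self.pdi!r}")
        if not math.isfinite(self.zeta_mv):
            raise ValidationError(f"zeta_mv must be finite, got {self.zeta_mv!r}")

    @property
    def label(self) -> tuple[float, float, float]:
        """(MWCO, time, force) triple identifying the condition."""
        return (self.mwco_kda, self.time_min, self.force_g)


@dataclass(frozen=True)
class RunConfig:
    """TOPSIS run configuration: criteria order, weights and directions."""

    criteria_order: tuple[str, ...] = CRITERIA
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    directions: tuple[str, ...] = DEFAULT_DIRECTIONS
    rounding_tolerance: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria_order", tuple(self.criteria_order))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "directions", tuple(self.directions))
        if len(self.weights) != len(self.criteria_order):
            raise ValidationError(
                f"{len(self.weights)} weights for {len(self.criteria_order)} criteria"
            )
        if len(self.directions) != len(self.criteria_order):
            raise ValidationError(
                f"{len(self.directions)} directions for {len(self.criteria_order)} criteria"
            )
        if any(w <= 0 for w in self.weights):
            raise ValidationError(f"all weights must be > 0, got {self.weights}")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1, got sum {sum(self.weights)!r}")
        for direction in self.directions:
            if direction not in ("benefit", "cost"):
                raise ValidationError(f"unknown criterion direction {direction!r}")
        if self.rounding_tolerance < 0:
            raise ValidationError("rounding_tolerance must be nonnegative")
        if self.seed < 0:
            raise ValidationError("seed must be nonnegative")


def _read_csv(path: str | Path, required: Sequence[str],
              optional: Sequence[str] = ()) -> pd.DataFrame:
    """Read a CSV, check the header (case-insensitively) and coerce numerics."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    for column in required:
        if column not in frame.columns:
            raise SchemaError(f"{path.name}: missing required column {column!r}")
    keep = list(required) + [c for c in optional if c in frame.columns]
    return frame[keep]


def _numeric(frame: pd.DataFrame, path: str | Path,
             skip: Sequence[str] = ()) -> pd.DataFrame:
    frame = frame.copy()
    for column in frame.columns:
        if column in skip:
            continue
        converted = pd.to_numeric(frame[column], errors="coerce")
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0])
            raise ParseError(
                f"{Path(path).name}: non-numeric value in column {column!r} at row {row}"
            )
        frame[column] = converted.astype(float)
    return frame


# ---------------------------------------------------------------------------
# conditions.csv


def read_condition_table(path: str | Path) -> list[ConditionRecord]:
    """Read a separation-condition table into validated records.

    Raises ``SchemaError`` for a missing column, ``ParseError`` for a
    non-numeric cell (with row index), and ``ValidationError`` for a
    duplicated (MWCO, time, force) triple or out-of-range value.  Row order
    is preserved.
    """
    frame = _numeric(_read_csv(path, _CONDITION_COLUMNS), path)
    records = [ConditionRecord(**row) for row in frame.to_dict("records")]
    seen: set[tuple[float, float, float]] = set()
    for record in records:
        if record.label in seen:
            raise ValidationError(
                f"duplicate condition triple (mwco, time, force) = {record.label}"
            )
        seen.add(record.label)
    return records


def write_condition_table(records: Sequence[ConditionRecord], path: str | Path) -> None:
    frame = pd.DataFrame([{c: getattr(r, c) for c in _CONDITION_COLUMNS} for r in records])
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# titration.csv


def read_titration_table(path: str | Path) -> pd.DataFrame:
    """Read quencher concentration (mol/L) vs fluorescence intensity."""
    frame = _numeric(_read_csv(path, ("q_mol_per_l", "intensity")), path)
    if not frame["q_mol_per_l"].is_monotonic_increasing:
        raise ValidationError("q_mol_per_l must be ascending")
    if (frame["intensity"] <= 0).any():
        raise ValidationError("intensities must be strictly positive")
    return frame


def write_titration_table(q, intensity, path: str | Path) -> None:
    pd.DataFrame({"q_mol_per_l": q, "intensity": intensity}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# energy_frames.csv


def read_energy_frames(path: str | Path) -> pd.DataFrame:
    """Read per-frame MM/GBSA component energies (kcal/mol)."""
    frame = _numeric(
        _read_csv(path, ("frame", "vdw", "ele", "gb", "surf"), optional=("internal",)),
        path,
    )
    return frame


def write_energy_frames(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sweep.csv


def read_sweep_table(path: str | Path) -> pd.DataFrame:
    """Read a stability sweep: x plus Z-average and/or count-rate columns."""
    frame = _numeric(
        _read_csv(path, ("x", "z_ave_nm"), optional=("count_rate_kcps",)), path
    )
    return frame


def write_sweep_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# composition.csv


def read_composition_table(path: str | Path) -> pd.DataFrame:
    """Read per-component, per-group summary statistics (mean, sd, n)."""
    frame = _numeric(
        _read_csv(path, ("component", "group", "mean", "sd", "n")),
        path,
        skip=("component", "group"),
    )
    if (frame["sd"] < 0).any():
        raise ValidationError("sd must be nonnegative")
    if (frame["n"] < 2).any():
        raise ValidationError("n must be at least 2 per group")
    frame["n"] = frame["n"].astype(int)
    return frame


def write_composition_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration (JSON)


def read_config(path: str | Path | None = None) -> RunConfig:
    """Load a JSON run configuration; absent keys fall back to defaults.

    An empty file/object (or ``path=None``) yields the study defaults:
    weights (0.15, 0.20, 0.25, 0.15, 0.25) over (z_ave, count_rate, pdi,
    zeta_abs, conductivity) with directions (cost, benefit, cost, benefit,
    cost).
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8").strip()
    raw = json.loads(text) if text else {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a JSON object")
    known = {"criteria_order", "weights", "directions", "rounding_tolerance", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    payload = {
        "criteria_order": list(config.criteria_order),
        "weights": list(config.weights),
        "directions": list(config.directions),
        "rounding_tolerance": config.rounding_tolerance,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
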