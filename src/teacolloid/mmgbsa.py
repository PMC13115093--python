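"""MM/GBSA energy bookkeeping.

The molecular mechanics / generalized Born surface area end-point method
decomposes a binding free energy into gas-phase and solvation terms
(kcal/mol):

    dE_gas  = dE_internal + dE_vdw + dE_ele
    dG_solv = dG_GB + dG_SA
    dG_bind = dE_gas + dG_solv

with the nonpolar solvation term taken proportional to the change in
solvent-accessible surface area, dG_SA = gamma * dSASA (gamma defaults to
0.0072 kcal·mol⁻¹·Å⁻² with SASA in Å²).  The entropic contribution −TΔS is
intentionally absent, and dE_internal defaults to 0 (single-trajectory
convention, where internal terms cancel between complex and parts).

This module does no simulation: it aggregates per-frame component tables,
derives totals, and validates printed decomposition tables for additivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from teacolloid.errors import ValidationError

#: Conventional nonpolar surface-tension coefficient, kcal·mol⁻¹·Å⁻².
DEFAULT_GAMMA = 0.0072


@dataclass(frozen=True)
class EnergyComponents:
    """Per-component MM/GBSA energies (kcal/mol)."""

    vdw: float
    ele: float
    gb: float
    surf: float
    internal: float = 0.0

    def __post_init__(self) -> None:
        for name in ("vdw", "ele", "gb", "surf", "internal"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"component {name!r} must be finite")


@dataclass(frozen=True)
class DecomposedEnergy:
    """Component energies plus derived gas/solvation/binding totals."""

    components: EnergyComponents
    gas: float = field(init=False)
    solv: float = field(init=False)
    bind: float = field(init=False)

    def __post_init__(self) -> None:
        c = self.components
        object.__setattr__(self, "gas", c.internal + c.vdw + c.ele)
        object.__setattr__(self, "solv", c.gb + c.surf)
        object.__setattr__(self, "bind", self.gas + self.solv)


def aggregate_components(frames: pd.DataFrame) -> tuple[EnergyComponents, dict[str, float]]:
    """Mean and standard error of each component over trajectory frames.

    ``frames`` follows the ``energy_frames.csv`` schema (vdw, ele, gb, surf
    and optionally internal).  With a single frame the SEM is 0 by
    convention.
    """
    if len(frames) == 0:
        raise ValidationError("energy table has no frames")
    names = ["vdw", "ele", "gb", "surf"] + (["internal"] if "internal" in frames else [])
    means = {}
    sems = {}
    n = len(frames)
    for name in names:
        column = frames[name].to_numpy(dtype=float)
        means[name] = float(column.mean())
        # constant columns get SEM exactly 0 (float summation would leave dust)
        if n == 1 or np.ptp(column) == 0:
            sems[name] = 0.0
        else:
            sems[name] = float(column.std(ddof=1) / math.sqrt(n))
    return EnergyComponents(**means), sems


def derive_totals(components: EnergyComponents) -> DecomposedEnergy:
    """Derive gas-phase, solvation and binding totals from components."""
    return DecomposedEnergy(components=components)


def nonpolar_solvation(delta_sasa: float, gamma: float = DEFAULT_GAMMA) -> float:
    """Nonpolar solvation energy gamma * dSASA (kcal/mol, SASA in Å²)."""
    if not (math.isfinite(delta_sasa) and math.isfinite(gamma)):
        raise ValidationError("delta_sasa and gamma must be finite")
    return gamma * delta_sasa


def binding_from_endpoints(
    complex_: DecomposedEnergy, receptor: DecomposedEnergy, ligand: DecomposedEnergy
) -> float:
    """End-point binding energy: G(complex) − [G(receptor) + G(ligand)]."""
    return complex_.bind - (receptor.bind + ligand.bind)


@dataclass(frozen=True)
class DecompositionCheck:
    label: str
    recomputed: DecomposedEnergy
    printed_gas: float
    printed_solv: float
    printed_bind: float
    gas_ok: bool
    solv_ok: bool
    bind_ok: bool

    @property
    def passed(self) -> bool:
        return self.gas_ok and self.solv_ok and self.bind_ok


@dataclass(frozen=True)
class DecompositionValidation:
    columns: tuple[DecompositionCheck, ...]
    tolerance: float

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.columns)

    @property
    def failures(self) -> tuple[DecompositionCheck, ...]:
        return tuple(c for c in self.columns if not c.passed)


def validate_decomposition_table(
    table: dict[str, dict[str, float]], tolerance: float = 0.015
) -> DecompositionValidation:
    """Check printed gas/solv/bind totals against recomputed component sums.

    ``table`` maps a column label (e.g. an interaction pair) to a dict with
    component keys (vdw, ele, gb, surf, optionally internal) and printed
    totals (gas, solv, bind).  The default tolerance 0.015 kcal/mol absorbs
    2-decimal rounding of the printed components.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be nonnegative")
    checks = []
    for label, entry in table.items():
        comps = EnergyComponents(
            vdw=entry["vdw"],
            ele=entry["ele"],
            gb=entry["gb"],
            surf=entry["surf"],
            internal=entry.get("internal", 0.0),
        )
        derived = derive_totals(comps)
        checks.append(
            DecompositionCheck(
                label=label,
                recomputed=derived,
                printed_gas=entry["gas"],
                printed_solv=entry["solv"],
                printed_bind=entry["bind"],
                gas_ok=abs(derived.gas - entry["gas"]) <= tolerance,
                solv_ok=abs(derived.solv - entry["solv"]) <= tolerance,
                bind_ok=abs(derived.bind - entry["bind"]) <= tolerance,
            )
        )
    return DecompositionValidation(columns=tuple(checks), tolerance=tolerance)
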