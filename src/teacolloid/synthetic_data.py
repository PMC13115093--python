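"""Seeded synthetic inputs for every analysis stage.

No raw instrument tables are published for the isolation campaign, so each
generator emulates the statistical structure its downstream stage assumes:

* ``gen_condition_table`` — a full-factorial 2 (MWCO) × 5 (force) × 3 (time)
  design of 30 separation conditions with additive per-criterion trends and
  Gaussian instrument noise, for the TOPSIS stage;
* ``gen_titration`` — fluorescence intensities under the Stern–Volmer or
  single-site binding law with multiplicative lognormal noise;
* ``gen_energy_frames`` — independent Gaussian per-frame MM/GBSA components;
* ``gen_sweep`` — linear ramps or threshold jumps over temperature/pH/day;
* ``gen_composition`` — Gaussian replicates from per-group (mean, SD, n).

Every generator is a pure function of (design, seed).  Randomness comes from
NumPy's PCG64 via ``default_rng([seed, stream])``, where ``stream`` is a
fixed per-generator offset, so different generators called with the same
seed draw independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from teacolloid.binding import TitrationSeries
from teacolloid.errors import DesignError
from teacolloid.mmgbsa import EnergyComponents
from teacolloid.stability import SweepSeries
from teacolloid.tabular_io import CRITERIA, ConditionRecord
from teacolloid.group_compare import CompositionSummary

# Fixed sub-stream offsets: generators with the same seed stay independent.
_STREAM = {"conditions": 0, "titration": 1, "energy": 2, "sweep": 3, "composition": 4}

#: Criterion baselines typical of a white-tea colloid retentate:
#: Z-average ~300 nm, count rate ~400 kcps, PDI ~0.28, |zeta| ~20 mV.
_DEFAULT_BASELINE = {
    "z_ave": 300.0,
    "count_rate": 400.0,
    "pdi": 0.28,
    "zeta_abs": 20.0,
    "conductivity": 120.0,
}

#: Additive trends per level index (mwco, force, time).  The looser membrane
#: (second MWCO level) yields smaller, more uniform, better-purified
#: retentates; stronger force grows particles and sheds conductivity.
_DEFAULT_EFFECTS = {
    "z_ave": (-40.0, 12.0, 5.0),
    "count_rate": (60.0, 10.0, -5.0),
    "pdi": (-0.05, 0.004, 0.002),
    "zeta_abs": (3.0, 0.4, 0.1),
    "conductivity": (-30.0, -4.0, -2.0),
}

#: Instrument-like noise magnitudes (same units as each criterion).
_DEFAULT_NOISE_SD = {
    "z_ave": 8.0,
    "count_rate": 12.0,
    "pdi": 0.01,
    "zeta_abs": 0.8,
    "conductivity": 3.0,
}


@dataclass(frozen=True)
class ConditionDesign:
    """Factorial design for the separation-condition table.

    ``effects[criterion]`` holds additive slopes per unit *level index*
    (0-based) along (mwco, force, time); the generated mean for a cell is
    ``baseline + mwco_idx*a + force_idx*b + time_idx*c``.
    """

    mwco_levels: tuple[float, ...] = (30.0, 100.0)
    force_levels: tuple[float, ...] = (2000.0, 3000.0, 4000.0, 5000.0, 6000.0)
    time_levels: tuple[float, ...] = (10.0, 20.0, 30.0)
    baseline: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINE))
    effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))

    def __post_init__(self) -> None:
        for name, levels in (
            ("mwco_levels", self.mwco_levels),
            ("force_levels", self.force_levels),
            ("time_levels", self.time_levels),
        ):
            if len(levels) == 0:
                raise DesignError(f"{name} must not be empty")
        for criterion in CRITERIA:
            if criterion not in self.baseline:
                raise DesignError(f"baseline missing criterion {criterion!r}")
            if float(self.noise_sd.get(criterion, 0.0)) < 0:
                raise DesignError(f"noise_sd[{criterion!r}] must be nonnegative")

    @property
    def size(self) -> int:
        return len(self.mwco_levels) * len(self.force_levels) * len(self.time_levels)


def gen_condition_table(
    design: ConditionDesign | None = None, seed: int = 0
) -> list[ConditionRecord]:
    """One record per factorial cell: baseline + trends + Gaussian noise.

    PDI is clipped to [0, 1] after noise; other criteria are floored at a
    small positive value so the type invariants hold.  The zeta criterion is
    generated as a magnitude and stored with negative sign (tea colloids are
    anionic).
    """
    design = design or ConditionDesign()
    rng = np.random.default_rng([_STREAM["conditions"], seed])
    records = []
    for i, mwco in enumerate(design.mwco_levels):
        for k, time in enumerate(design.time_levels):
            for j, force in enumerate(design.force_levels):
                values = {}
                for criterion in CRITERIA:
                    a, b, c = design.effects.get(criterion, (0.0, 0.0, 0.0))
                    mean = design.baseline[criterion] + a * i + b * j + c * k
                    sd = float(design.noise_sd.get(criterion, 0.0))
                    value = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    if criterion == "pdi":
                        value = float(np.clip(value, 0.0, 1.0))
                    else:
                        value = max(value, 1e-6)
                    values[criterion] = value
                records.append(
                    ConditionRecord(
                        mwco_kda=mwco,
                        time_min=time,
                        force_g=force,
                        z_ave_nm=values["z_ave"],
                        count_rate_kcps=values["count_rate"],
                        pdi=values["pdi"],
                        zeta_mv=-values["zeta_abs"],
                        conductivity=values["conductivity"],
                    )
                )
    return records


@dataclass(frozen=True)
class TitrationDesign:
    """Ground truth for a synthetic fluorescence titration.

    Defaults mirror the gallic-acid / BP-complex system: F0 = 8608 a.u.,
    quencher grid 0.1–10 × 10⁻⁷ mol/L, K_SV = 7.6 × 10⁶ L/mol,
    K_a = 1.43 × 10⁶ L/mol with n = 1.
    """

    f0: float = 8608.0
    q_grid: tuple[float, ...] = tuple(np.linspace(0.1e-7, 10e-7, 10))
    ksv_true: float = 7.6e6
    ka_true: float = 1.43e6
    n_true: float = 1.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        if q.size < 3:
            raise DesignError("q_grid needs at least 3 concentrations")
        if (q < 0).any() or (np.diff(q) <= 0).any():
            raise DesignError("q_grid must be nonnegative and strictly increasing")
        if self.f0 <= 0 or self.ksv_true <= 0 or self.ka_true <= 0 or self.n_true <= 0:
            raise DesignError("f0, ksv_true, ka_true, n_true must be positive")
        if self.noise_cv < 0:
            raise DesignError("noise_cv must be nonnegative")


def gen_titration(
    design: TitrationDesign | None = None,
    law: str = "stern_volmer",
    seed: int = 0,
) -> TitrationSeries:
    """Intensities under the chosen quenching law with lognormal noise.

    ``stern_volmer``: F = F0 / (1 + K_SV·[Q]);
    ``binding_site``: F = F0 / (1 + K_a·[Q]^n).
    Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` (keeps intensities positive); F0 is returned noise-free.
    """
    design = design or TitrationDesign()
    q = np.asarray(design.q_grid, dtype=float)
    if law == "stern_volmer":
        f = design.f0 / (1.0 + design.ksv_true * q)
    elif law == "binding_site":
        with np.errstate(divide="ignore"):
            ka_qn = np.where(q > 0, design.ka_true * q**design.n_true, 0.0)
        f = design.f0 / (1.0 + ka_qn)
    else:
        raise DesignError(f"unknown quenching law {law!r}")
    if design.noise_cv > 0:
        rng = np.random.default_rng([_STREAM["titration"], seed])
        sigma = np.sqrt(np.log1p(design.noise_cv**2))
        f = f * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=f.shape)
    return TitrationSeries(f0=design.f0, q=q, f=f)


def gen_energy_frames(
    means: EnergyComponents,
    sds: Mapping[str, float],
    n_frames: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frame Gaussian component energies around the given means."""
    if n_frames < 1:
        raise DesignError("n_frames must be at least 1")
    rng = np.random.default_rng([_STREAM["energy"], seed])
    data = {"frame": np.arange(n_frames)}
    for name in ("vdw", "ele", "gb", "surf"):
        sd = float(sds.get(name, 0.0))
        if sd < 0:
            raise DesignError(f"sd[{name!r}] must be nonnegative")
        mean = getattr(means, name)
        data[name] = (
            rng.normal(mean, sd, size=n_frames) if sd > 0 else np.full(n_frames, mean)
        )
    return pd.DataFrame(data)


def gen_sweep(
    x_grid: Sequence[float],
    baseline: float,
    delta: float,
    shape: str = "linear",
    noise_sd: float = 0.0,
    seed: int = 0,
    axis: str = "temperature_C",
    knot: float | None = None,
    ylabel: str = "z_ave_nm",
) -> SweepSeries:
    """A stability sweep ramping (``linear``) or jumping (``threshold``).

    Linear: y runs from ``baseline`` to ``baseline + delta`` across the
    grid.  Threshold: y sits at ``baseline`` until x passes ``knot``
    (default: the grid midpoint), then at ``baseline + delta``.
    """
    x = np.asarray(x_grid, dtype=float)
    if x.size < 2:
        raise DesignError("a sweep needs at least 2 x points")
    if shape == "linear":
        y = baseline + delta * np.linspace(0.0, 1.0, x.size)
    elif shape == "threshold":
        cut = knot if knot is not None else 0.5 * (x[0] + x[-1])
        y = np.where(x <= cut, baseline, baseline + delta) if x[0] < x[-1] else np.where(
            x >= cut, baseline, baseline + delta
        )
        y = y.astype(float)
    else:
        raise DesignError(f"unknown sweep shape {shape!r}")
    if noise_sd < 0:
        raise DesignError("noise_sd must be nonnegative")
    if noise_sd > 0:
        rng = np.random.default_rng([_STREAM["sweep"], seed])
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.maximum(y, 1e-6)
    return SweepSeries(axis=axis, x=x, y=y, ylabel=ylabel)


def gen_composition(
    groups: Sequence[CompositionSummary], seed: int = 0
) -> pd.DataFrame:
    """Gaussian replicates with each group's stated mean, SD and n.

    Returns a long table (component, group, replicate, value).  A zero SD
    with n > 1 is rejected — it would make downstream test statistics
    degenerate by construction.
    """
    rng = np.random.default_rng([_STREAM["composition"], seed])
    rows = []
    for summary in groups:
        if summary.sd <= 0 and summary.n > 1:
            raise DesignError(
                f"{summary.component}/{summary.group}: SD must be positive for n > 1"
            )
        draws = rng.normal(summary.mean, summary.sd, size=summary.n)
        for r, value in enumerate(draws):
            rows.append(
                {
                    "component": summary.component,
                    "group": summary.group,
                    "replicate": r,
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows, columns=["component", "group", "replicate", "value"])
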