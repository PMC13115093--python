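"""Fluorescence-quenching binding analysis.

Two classical models are fitted to a titration of a fluorophore (here the
BSA–pectin "BP" complex) with a small-molecule quencher (gallic acid or
caffeine):

* Stern–Volmer:  F0/F = 1 + K_SV·[Q], fitted as a straight line of F0/F
  against [Q]; the slope is the Stern–Volmer quenching constant K_SV
  (L/mol).
* Double-logarithmic: lg(F0/F − 1) = lg K_a + n·lg[Q]; the intercept gives
  the apparent binding constant K_a (L/mol) and the slope the number of
  binding sites n.

All logarithms are base 10 and concentrations are mol/L.  No inner-filter
correction is applied; the Stern–Volmer intercept is left free and reported
so departures from 1 (baseline or inner-filter artefacts) are visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from teacolloid.errors import ValidationError


@dataclass(frozen=True)
class TitrationSeries:
    """Quencher concentrations (mol/L) vs fluorescence intensities (a.u.)."""

    f0: float
    q: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "f", f)
        if self.f0 <= 0:
            raise ValidationError("f0 must be positive")
        if q.shape != f.shape or q.ndim != 1:
            raise ValidationError("q and f must be 1-D arrays of equal length")
        if q.size < 3:
            raise ValidationError("a titration needs at least 3 points")
        if (np.diff(q) <= 0).any():
            raise ValidationError("q must be strictly increasing")
        if (q < 0).any():
            raise ValidationError("q must be nonnegative")
        if (f <= 0).any():
            raise ValidationError("intensities must be strictly positive")


@dataclass(frozen=True)
class QuenchingFit:
    """Stern–Volmer fit: K_SV (L/mol), intercept and goodness of fit."""

    ksv: float
    intercept: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class BindingFit:
    """Double-logarithmic fit: lg K_a, K_a (L/mol), binding-site number n."""

    lg_ka: float
    ka: float
    n_sites: float
    r2: float
    n_points_used: int
    excluded: tuple[int, ...] = ()


def predict_quench(ksv: float, q) -> np.ndarray | float:
    """Stern–Volmer ratio F0/F = 1 + K_SV·[Q]."""
    q_arr = np.asarray(q, dtype=float)
    if ksv < 0:
        raise ValidationError("ksv must be nonnegative")
    if (q_arr < 0).any():
        raise ValidationError("q must be nonnegative")
    out = 1.0 + ksv * q_arr
    return float(out) if np.isscalar(q) or out.ndim == 0 else out


def stern_volmer_fit(series: TitrationSeries) -> QuenchingFit:
    """Least-squares Stern–Volmer fit of F0/F against [Q].

    The intercept is free (ideally close to 1); K_SV is the slope.
    """
    x = series.q
    y = series.f0 / series.f
    if np.ptp(x) == 0:
        raise ValidationError("q has zero variance; slope undefined")
    fit = stats.linregress(x, y)
    return QuenchingFit(
        ksv=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_points=int(x.size),
    )


def double_log_fit(series: TitrationSeries) -> BindingFit:
    """Fit lg(F0/F − 1) = lg K_a + n·lg[Q] by ordinary least squares.

    Points with F0/F − 1 ≤ 0 (no net quenching) or [Q] = 0 have no
    logarithm and are excluded; their indices are reported on the result.
    Raises if fewer than 3 usable points remain.
    """
    ratio_minus_1 = series.f0 / series.f - 1.0
    usable = (ratio_minus_1 > 0) & (series.q > 0)
    excluded = tuple(int(i) for i in np.nonzero(~usable)[0])
    if usable.sum() < 3:
        raise ValidationError(
            f"only {int(usable.sum())} usable points after excluding indices "
            f"{list(excluded)} (need >= 3)"
        )
    x = np.log10(series.q[usable])
    y = np.log10(ratio_minus_1[usable])
    fit = stats.linregress(x, y)
    lg_ka = float(fit.intercept)
    return BindingFit(
        lg_ka=lg_ka,
        ka=10.0**lg_ka,
        n_sites=float(fit.slope),
        r2=float(fit.rvalue**2),
        n_points_used=int(usable.sum()),
        excluded=excluded,
    )
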