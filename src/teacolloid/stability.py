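"""Colloidal stability-sweep metrics.

Environmental stability of a colloid is probed by sweeping one axis —
temperature (10–70 °C heating/cooling), pH (3–12), cold-storage day or
freeze–thaw cycle — and recording the Z-average diameter (nm) or count rate
(kcps).  "How much the system changed" is summarised two ways, side by side:

* ``endpoint_delta`` — |y_last − y_first|, change over the whole sweep;
* ``range`` — max(y) − min(y), the widest excursion anywhere in the sweep.

Two systems on the same axis are compared by range: the one with the
smaller range is flagged as the more stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from teacolloid.errors import ValidationError

SWEEP_AXES = ("temperature_C", "pH", "day")


@dataclass(frozen=True)
class SweepSeries:
    """Ordered stability measurements along one environmental axis."""

    axis: str
    x: np.ndarray
    y: np.ndarray
    ylabel: str = "z_ave_nm"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.axis not in SWEEP_AXES:
            raise ValidationError(f"axis must be one of {SWEEP_AXES}, got {self.axis!r}")
        if x.shape != y.shape or x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValidationError("a sweep needs at least 2 points")
        dx = np.diff(x)
        if not ((dx > 0).all() or (dx < 0).all()):
            raise ValidationError("x must be strictly monotone (heating or cooling)")
        if (y <= 0).any():
            raise ValidationError("measurements must be strictly positive")


@dataclass(frozen=True)
class SweepMetrics:
    endpoint_delta: float
    range: float
    min: float
    max: float
    argmin_x: float
    argmax_x: float


def sweep_delta(series: SweepSeries) -> SweepMetrics:
    """Endpoint change and full excursion range of a sweep."""
    y = series.y
    i_min = int(np.argmin(y))
    i_max = int(np.argmax(y))
    return SweepMetrics(
        endpoint_delta=float(abs(y[-1] - y[0])),
        range=float(y[i_max] - y[i_min]),
        min=float(y[i_min]),
        max=float(y[i_max]),
        argmin_x=float(series.x[i_min]),
        argmax_x=float(series.x[i_max]),
    )


def ph_window(series: SweepSeries) -> dict[str, float]:
    """Size window over a pH sweep: min, max and span = max − min."""
    if series.axis != "pH":
        raise ValidationError(f"ph_window requires a pH sweep, got axis {series.axis!r}")
    y_min = float(series.y.min())
    y_max = float(series.y.max())
    return {"y_min": y_min, "y_max": y_max, "span": y_max - y_min}


@dataclass(frozen=True)
class SweepComparison:
    metrics_a: SweepMetrics
    metrics_b: SweepMetrics
    more_stable: str  # "a", "b" or "tie"


def compare_sweeps(a: SweepSeries, b: SweepSeries) -> SweepComparison:
    """Compare two systems swept along the same axis by excursion range.

    The x grids need not coincide; the comparison is metric-level only
    (no interpolation).
    """
    if a.axis != b.axis:
        raise ValidationError(f"axis mismatch: {a.axis!r} vs {b.axis!r}")
    if a.ylabel != b.ylabel:
        raise ValidationError(f"ylabel mismatch: {a.ylabel!r} vs {b.ylabel!r}")
    metrics_a = sweep_delta(a)
    metrics_b = sweep_delta(b)
    if metrics_a.range < metrics_b.range:
        verdict = "a"
    elif metrics_b.range < metrics_a.range:
        verdict = "b"
    else:
        verdict = "tie"
    return SweepComparison(metrics_a=metrics_a, metrics_b=metrics_b, more_stable=verdict)
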