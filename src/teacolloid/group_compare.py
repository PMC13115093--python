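"""Two-group comparison of composition measurements.

Component concentrations (protein, polysaccharide, tea polyphenol, caffeine,
gallic acid; μg/mg dry mass) in the parent tea colloid versus the isolated
nanoparticle fraction are compared with Welch's unequal-variance t-test
computed from summary statistics (mean, SD, n — typically n = 3 triplicates):

    t  = (m_a − m_b) / sqrt(s_a²/n_a + s_b²/n_b)
    df = Welch–Satterthwaite approximation
    p  = two-sided tail of Student's t at df

The Welch form (rather than the pooled-variance t) is what reproduces the
reported p-values when group SDs differ; both routes — summary statistics or
raw replicates — give identical results by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from teacolloid.errors import ValidationError


@dataclass(frozen=True)
class CompositionSummary:
    """Per-component, per-group summary: mean, SD (μg/mg) and group size."""

    component: str
    group: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("n must be at least 2")
        if self.sd < 0:
            raise ValidationError("sd must be nonnegative")


@dataclass(frozen=True)
class TestResult:
    """Welch t-test outcome: statistic, Satterthwaite df, two-sided p."""

    t_stat: float
    df: float
    p_two_sided: float


def welch_t_from_summary(a: CompositionSummary, b: CompositionSummary) -> TestResult:
    """Welch's t-test from two (mean, SD, n) summaries of the same component.

    Degenerate data: both SDs zero with equal means gives p = 1 by
    convention; both SDs zero with unequal means leaves the statistic
    undefined and raises.
    """
    if a.component != b.component:
        raise ValidationError(
            f"cannot compare different components {a.component!r} vs {b.component!r}"
        )
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TestResult(t_stat=0.0, df=float(a.n + b.n - 2), p_two_sided=1.0)
        raise ValidationError(
            "both groups have zero SD but different means: t undefined"
        )
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(t_stat=float(t), df=float(df), p_two_sided=float(p))


def welch_t_from_replicates(x: Sequence[float], y: Sequence[float],
                            component: str = "sample") -> TestResult:
    """Welch's t-test on raw replicates; delegates through the summary route."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 replicates")
    a = CompositionSummary(component, "x", float(x.mean()), float(x.std(ddof=1)), int(x.size))
    b = CompositionSummary(component, "y", float(y.mean()), float(y.std(ddof=1)), int(y.size))
    return welch_t_from_summary(a, b)


def compare_composition_table(
    summaries: Sequence[CompositionSummary],
) -> pd.DataFrame:
    """One Welch test per component from a list of two-group summaries.

    Each component must appear in exactly two distinct groups; output rows
    preserve the order components first appear in the input.
    """
    by_component: dict[str, list[CompositionSummary]] = {}
    for summary in summaries:
        by_component.setdefault(summary.component, []).append(summary)
    rows = []
    for component, pair in by_component.items():
        if len(pair) != 2:
            raise ValidationError(
                f"component {component!r} appears in {len(pair)} group(s); expected 2"
            )
        a, b = pair
        if a.group == b.group:
            raise ValidationError(
                f"component {component!r} has a duplicated group label {a.group!r}"
            )
        result = welch_t_from_summary(a, b)
        rows.append(
            {
                "component": component,
                "group_a": a.group,
                "group_b": b.group,
                "t_stat": result.t_stat,
                "df": result.df,
                "p_two_sided": result.p_two_sided,
            }
        )
    columns = ["component", "group_a", "group_b", "t_stat", "df", "p_two_sided"]
    return pd.DataFrame(rows, columns=columns)
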