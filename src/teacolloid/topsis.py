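"""TOPSIS ranking of separation conditions.

The Technique for Order Preference by Similarity to Ideal Solution ranks the
m = 30 ultrafiltration–centrifugation conditions on n = 5 colloidal criteria
(Z-average, count rate, PDI, |zeta potential|, conductivity) in six steps:

1. build the m×n decision matrix X (the zeta column stores |zeta|);
2. vector-normalise each column, Z_ij = X_ij / sqrt(sum_i X_ij^2);
3. weight, U_ij = Z_ij * w_j;
4. pick the positive/negative ideal vectors A+/A- per criterion — for a
   benefit criterion A+ takes the column maximum, for a cost criterion the
   minimum (and vice versa for A-);
5. Euclidean separations d_i± = ||U_i - A±||;
6. closeness C_i = d_i- / (d_i+ + d_i-); rank 1 is the largest C.

Lower Z-average, PDI and conductivity are favourable (cost criteria);
higher count rate and |zeta| are favourable — that direction handling is
applied in step 4 rather than by pre-transforming the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from teacolloid.errors import ValidationError
from teacolloid.tabular_io import ConditionRecord, RunConfig


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives × criteria table with per-criterion directions/weights."""

    alternative_labels: tuple[tuple[float, float, float], ...]
    criteria: tuple[str, ...]
    values: np.ndarray  # m×n, X_ij
    directions: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        m, n = values.shape
        if m < 2 or n < 1:
            raise ValidationError(f"decision matrix must be at least 2×1, got {m}×{n}")
        if np.isnan(values).any():
            raise ValidationError("decision matrix contains NaN")
        if len(self.alternative_labels) != m:
            raise ValidationError("label count does not match row count")
        if not (len(self.criteria) == len(self.directions) == len(self.weights) == n):
            raise ValidationError("criteria/directions/weights length mismatch")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")


@dataclass(frozen=True)
class TopsisResult:
    """All intermediate arrays plus closeness and ranking."""

    matrix: DecisionMatrix
    normalized: np.ndarray
    weighted: np.ndarray
    ideal_pos: np.ndarray
    ideal_neg: np.ndarray
    d_pos: np.ndarray
    d_neg: np.ndarray
    closeness: np.ndarray
    rank: np.ndarray
    ties: tuple[tuple[int, ...], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        """Tabulate labels, separations, closeness and rank."""
        labels = self.matrix.alternative_labels
        return pd.DataFrame(
            {
                "mwco_kda": [lab[0] for lab in labels],
                "time_min": [lab[1] for lab in labels],
                "force_g": [lab[2] for lab in labels],
                "d_pos": self.d_pos,
                "d_neg": self.d_neg,
                "closeness": self.closeness,
                "rank": self.rank,
            }
        )


def build_decision_matrix(
    records: Sequence[ConditionRecord], config: RunConfig | None = None
) -> DecisionMatrix:
    """Assemble the decision matrix from condition records.

    Columns follow ``config.criteria_order`` (default: z_ave, count_rate,
    pdi, zeta_abs, conductivity); the zeta column stores the absolute value
    of the measured zeta potential.
    """
    config = config or RunConfig()
    if len(records) < 2:
        raise ValidationError("ranking needs at least 2 alternatives")
    column_source = {
        "z_ave": lambda r: r.z_ave_nm,
        "count_rate": lambda r: r.count_rate_kcps,
        "pdi": lambda r: r.pdi,
        "zeta_abs": lambda r: abs(r.zeta_mv),
        "conductivity": lambda r: r.conductivity,
    }
    unknown = [c for c in config.criteria_order if c not in column_source]
    if unknown:
        raise ValidationError(f"unknown criteria: {unknown}")
    values = np.array(
        [[column_source[c](r) for c in config.criteria_order] for r in records]
    )
    return DecisionMatrix(
        alternative_labels=tuple(r.label for r in records),
        criteria=tuple(config.criteria_order),
        values=values,
        directions=config.directions,
        weights=config.weights,
    )


def normalize(matrix: DecisionMatrix) -> np.ndarray:
    """Column-wise vector (Euclidean) normalisation of the decision matrix."""
    norms = np.linalg.norm(matrix.values, axis=0)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise ValidationError(
            f"criterion {matrix.criteria[zero[0]]!r} is all zeros; cannot normalise"
        )
    return matrix.values / norms


def apply_weights(normalized: np.ndarray, weights: Sequence[float]) -> np.ndarray:
    """Scale each normalised column by its criterion weight."""
    normalized = np.asarray(normalized, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if normalized.shape[1] != weights.shape[0]:
        raise ValidationError(
            f"{normalized.shape[1]} columns but {weights.shape[0]} weights"
        )
    return normalized * weights


def ideal_solutions(
    weighted: np.ndarray, directions: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative ideal vectors under benefit/cost directions."""
    weighted = np.asarray(weighted, dtype=float)
    col_max = weighted.max(axis=0)
    col_min = weighted.min(axis=0)
    a_pos = np.empty(weighted.shape[1])
    a_neg = np.empty(weighted.shape[1])
    for j, direction in enumerate(directions):
        if direction == "benefit":
            a_pos[j], a_neg[j] = col_max[j], col_min[j]
        elif direction == "cost":
            a_pos[j], a_neg[j] = col_min[j], col_max[j]
        else:
            raise ValidationError(f"unknown criterion direction {direction!r}")
    return a_pos, a_neg


def separation_distances(
    weighted: np.ndarray, ideals: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance of every alternative to each ideal vector."""
    weighted = np.asarray(weighted, dtype=float)
    a_pos, a_neg = (np.asarray(a, dtype=float) for a in ideals)
    if weighted.shape[1] != a_pos.shape[0] or weighted.shape[1] != a_neg.shape[0]:
        raise ValidationError("ideal vector length does not match criterion count")
    d_pos = np.linalg.norm(weighted - a_pos, axis=1)
    d_neg = np.linalg.norm(weighted - a_neg, axis=1)
    return d_pos, d_neg


def closeness(d_pos: np.ndarray, d_neg: np.ndarray) -> np.ndarray:
    """Relative closeness C = d- / (d+ + d-), with C = 0.5 where both are 0.

    The degenerate case (an alternative coincides with both ideals, i.e.
    all alternatives identical in every criterion) is assigned the limiting
    value 0.5 along d+ = d- and a warning is emitted.
    """
    d_pos = np.asarray(d_pos, dtype=float)
    d_neg = np.asarray(d_neg, dtype=float)
    if (d_pos < 0).any() or (d_neg < 0).any():
        raise ValidationError("separation distances must be nonnegative")
    total = d_pos + d_neg
    degenerate = total == 0
    if degenerate.any():
        warnings.warn(
            "alternative(s) equidistant at zero from both ideals; closeness set to 0.5",
            stacklevel=2,
        )
    out = np.full_like(d_pos, 0.5)
    np.divide(d_neg, total, out=out, where=~degenerate)
    return out


def rank_alternatives(c: np.ndarray) -> np.ndarray:
    """Competition ranking of closeness: rank 1 = largest C, ties share it."""
    c = np.asarray(c, dtype=float)
    if not np.isfinite(c).all():
        raise ValidationError("closeness values must be finite")
    # rank_i = 1 + number of strictly larger values (min-rank for ties)
    return 1 + (c[:, None] < c[None, :]).sum(axis=1)


def _tie_groups(rank: np.ndarray) -> tuple[tuple[int, ...], ...]:
    groups = []
    for value in np.unique(rank):
        members = np.nonzero(rank == value)[0]
        if members.size > 1:
            groups.append(tuple(int(i) for i in members))
    return tuple(groups)


def run_topsis(
    records: Sequence[ConditionRecord], config: RunConfig | None = None
) -> TopsisResult:
    """Run the full six-step procedure on condition records."""
    config = config or RunConfig()
    matrix = build_decision_matrix(records, config)
    z = normalize(matrix)
    u = apply_weights(z, matrix.weights)
    ideals = ideal_solutions(u, matrix.directions)
    d_pos, d_neg = separation_distances(u, ideals)
    c = closeness(d_pos, d_neg)
    rank = rank_alternatives(c)
    return TopsisResult(
        matrix=matrix,
        normalized=z,
        weighted=u,
        ideal_pos=ideals[0],
        ideal_neg=ideals[1],
        d_pos=d_pos,
        d_neg=d_neg,
        closeness=c,
        rank=rank,
        ties=_tie_groups(rank),
    )


@dataclass(frozen=True)
class ClosenessCheckRow:
    index: int
    c_recomputed: float
    c_printed: float
    passed: bool


@dataclass(frozen=True)
class ClosenessValidation:
    """Outcome of checking a printed closeness table for self-consistency."""

    rows: tuple[ClosenessCheckRow, ...]
    rank_order_ok: bool
    tolerance: float

    @property
    def all_pass(self) -> bool:
        return self.rank_order_ok and all(r.passed for r in self.rows)

    @property
    def failures(self) -> tuple[ClosenessCheckRow, ...]:
        return tuple(r for r in self.rows if not r.passed)


def validate_closeness_table(
    table: pd.DataFrame, tolerance: float = 0.001
) -> ClosenessValidation:
    """Check that a printed (d+, d-, C, rank) table is internally consistent.

    Per row, C is recomputed as d-/(d+ + d-) and compared with the printed
    value at ``tolerance`` (default 0.001, matching 4-decimal rounding of
    the separations).  Globally, the printed ranking must equal the
    descending order of printed C.

    ``table`` needs columns ``d_pos``, ``d_neg``, ``c``, ``rank``.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be nonnegative")
    for column in ("d_pos", "d_neg", "c", "rank"):
        if column not in table.columns:
            raise ValidationError(f"closeness table missing column {column!r}")
    rows = []
    for i, row in enumerate(table.itertuples(index=False)):
        c_re = float(row.d_neg) / (float(row.d_pos) + float(row.d_neg))
        rows.append(
            ClosenessCheckRow(
                index=i,
                c_recomputed=c_re,
                c_printed=float(row.c),
                passed=abs(c_re - float(row.c)) <= tolerance,
            )
        )
    printed_rank = table["rank"].to_numpy()
    expected_rank = rank_alternatives(table["c"].to_numpy(dtype=float))
    rank_ok = bool((printed_rank == expected_rank).all())
    return ClosenessValidation(rows=tuple(rows), rank_order_ok=rank_ok, tolerance=tolerance)
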