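"""TOPSIS: step identities, brute-force oracle equivalence, table validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teacolloid import synthetic_data, topsis
from teacolloid.errors import ValidationError
from teacolloid.tabular_io import ConditionRecord, RunConfig


def brute_force_topsis(values, weights, directions):
    """Independent six-step reference implementation in plain Python loops."""
    m = len(values)
    n = len(values[0])
    z = [[0.0] * n for _ in range(m)]
    for j in range(n):
        norm = math.sqrt(sum(values[i][j] ** 2 for i in range(m)))
        for i in range(m):
            z[i][j] = values[i][j] / norm
    u = [[z[i][j] * weights[j] for j in range(n)] for i in range(m)]
    a_pos, a_neg = [], []
    for j in range(n):
        column = [u[i][j] for i in range(m)]
        if directions[j] == "benefit":
            a_pos.append(max(column))
            a_neg.append(min(column))
        else:
            a_pos.append(min(column))
            a_neg.append(max(column))
    d_pos = [math.sqrt(sum((u[i][j] - a_pos[j]) ** 2 for j in range(n))) for i in range(m)]
    d_neg = [math.sqrt(sum((u[i][j] - a_neg[j]) ** 2 for j in range(n))) for i in range(m)]
    c = [d_neg[i] / (d_pos[i] + d_neg[i]) for i in range(m)]
    return d_pos, d_neg, c


def make_record(z=300.0, cr=400.0, pdi=0.25, zeta=-20.0, cond=100.0,
                mwco=100.0, time=20.0, force=3000.0):
    return ConditionRecord(mwco_kda=mwco, time_min=time, force_g=force,
                           z_ave_nm=z, count_rate_kcps=cr, pdi=pdi,
                           zeta_mv=zeta, conductivity=cond)


class TestSteps:
    def test_normalize_three_four_five(self):
        matrix = topsis.DecisionMatrix(
            alternative_labels=((1, 1, 1), (2, 2, 2)),
            criteria=("a",), values=np.array([[3.0], [4.0]]),
            directions=("benefit",), weights=(1.0,),
        )
        np.testing.assert_allclose(topsis.normalize(matrix), [[0.6], [0.8]])

    def test_normalize_equal_column(self):
        matrix = topsis.DecisionMatrix(
            alternative_labels=tuple((i, i, i) for i in range(4)),
            criteria=("a",), values=np.full((4, 1), 7.0),
            directions=("benefit",), weights=(1.0,),
        )
        np.testing.assert_allclose(topsis.normalize(matrix), np.full((4, 1), 0.5))

    def test_normalized_columns_have_unit_norm(self, rng):
        values = rng.uniform(0.1, 10, size=(30, 5))
        matrix = topsis.DecisionMatrix(
            alternative_labels=tuple((i, 0, 0) for i in range(30)),
            criteria=tuple("abcde"), values=values,
            directions=("benefit",) * 5, weights=(0.2,) * 5,
        )
        norms = np.linalg.norm(topsis.normalize(matrix), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_ideal_solutions_directions(self):
        u = np.array([[0.1, 0.1], [0.3, 0.3]])
        a_pos, a_neg = topsis.ideal_solutions(u, ("benefit", "cost"))
        np.testing.assert_allclose(a_pos, [0.3, 0.1])
        np.testing.assert_allclose(a_neg, [0.1, 0.3])

    def test_separation_three_four_five(self):
        u = np.array([[0.0, 0.0], [3.0, 4.0]])
        d_pos, d_neg = topsis.separation_distances(u, (np.array([3.0, 4.0]),
                                                       np.array([0.0, 0.0])))
        assert d_pos[0] == pytest.approx(5.0)
        assert d_pos[1] == 0.0
        assert d_neg[0] == 0.0

    def test_closeness_printed_best_row(self):
        c = topsis.closeness(np.array([0.0262]), np.array([0.0746]))
        assert c[0] == pytest.approx(0.7404, abs=0.001)

    def test_closeness_edge_cases(self):
        assert topsis.closeness(np.array([0.3]), np.array([0.0]))[0] == 0.0
        assert topsis.closeness(np.array([0.2]), np.array([0.2]))[0] == 0.5
        with pytest.warns(UserWarning):
            assert topsis.closeness(np.array([0.0]), np.array([0.0]))[0] == 0.5
        with pytest.raises(ValidationError):
            topsis.closeness(np.array([-0.1]), np.array([0.2]))

    def test_rank_alternatives(self):
        np.testing.assert_array_equal(
            topsis.rank_alternatives(np.array([0.2, 0.9, 0.5])), [3, 1, 2]
        )
        np.testing.assert_array_equal(
            topsis.rank_alternatives(np.array([0.4, 0.4, 0.4])), [1, 1, 1]
        )

    def test_zeta_stored_as_absolute_value(self):
        records = [make_record(zeta=-25.0), make_record(zeta=10.0, force=4000)]
        matrix = topsis.build_decision_matrix(records)
        zeta_col = list(matrix.criteria).index("zeta_abs")
        np.testing.assert_allclose(matrix.values[:, zeta_col], [25.0, 10.0])

    def test_single_record_is_an_error(self):
        with pytest.raises(ValidationError):
            topsis.build_decision_matrix([make_record()])


class TestPipeline:
    def test_hand_computed_two_by_two(self):
        # 2 alternatives x 2 criteria, both benefit, equal weights
        values = [[3.0, 1.0], [4.0, 2.0]]
        d_pos, d_neg, c_expected = brute_force_topsis(
            values, [0.5, 0.5], ["benefit", "benefit"]
        )
        matrix = topsis.DecisionMatrix(
            alternative_labels=((1, 1, 1), (2, 2, 2)),
            criteria=("a", "b"), values=np.array(values),
            directions=("benefit", "benefit"), weights=(0.5, 0.5),
        )
        z = topsis.normalize(matrix)
        u = topsis.apply_weights(z, matrix.weights)
        ideals = topsis.ideal_solutions(u, matrix.directions)
        dp, dn = topsis.separation_distances(u, ideals)
        c = topsis.closeness(dp, dn)
        np.testing.assert_allclose(dp, d_pos, atol=1e-12)
        np.testing.assert_allclose(dn, d_neg, atol=1e-12)
        np.testing.assert_allclose(c, c_expected, atol=1e-12)

    def test_oracle_equivalence_on_random_matrices(self, rng):
        """run_topsis matches the independent brute-force oracle to 1e-10."""
        for _ in range(120):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(1, 5))
            values = rng.uniform(0.1, 10.0, size=(m, n))
            raw_weights = rng.uniform(0.1, 1.0, size=n)
            weights = raw_weights / raw_weights.sum()
            directions = [str(rng.choice(["benefit", "cost"])) for _ in range(n)]
            matrix = topsis.DecisionMatrix(
                alternative_labels=tuple((i, 0, 0) for i in range(m)),
                criteria=tuple(f"c{j}" for j in range(n)),
                values=values, directions=tuple(directions), weights=tuple(weights),
            )
            z = topsis.normalize(matrix)
            u = topsis.apply_weights(z, weights)
            dp, dn = topsis.separation_distances(
                u, topsis.ideal_solutions(u, directions)
            )
            c = topsis.closeness(dp, dn)
            dp_o, dn_o, c_o = brute_force_topsis(values.tolist(), weights, directions)
            np.testing.assert_allclose(dp, dp_o, atol=1e-10)
            np.testing.assert_allclose(dn, dn_o, atol=1e-10)
            np.testing.assert_allclose(c, c_o, atol=1e-10)
            assert (c >= 0).all() and (c <= 1).all()

    def test_planted_dominant_condition_ranks_first(self, condition_records):
        # best value in every criterion direction: small size/PDI/conductivity,
        # large count rate and |zeta|
        dominant = make_record(z=50.0, cr=900.0, pdi=0.05, zeta=-45.0, cond=10.0,
                               mwco=999.0, time=99.0, force=9999.0)
        result = topsis.run_topsis(list(condition_records) + [dominant])
        assert result.rank[-1] == 1
        assert result.closeness[-1] > np.max(result.closeness[:-1])

    def test_permuting_rows_preserves_label_to_closeness_map(self, condition_records, rng):
        result = topsis.run_topsis(condition_records)
        order = rng.permutation(len(condition_records))
        shuffled = [condition_records[i] for i in order]
        result_shuffled = topsis.run_topsis(shuffled)
        mapping = dict(zip(result.matrix.alternative_labels, result.closeness))
        for label, c in zip(result_shuffled.matrix.alternative_labels,
                            result_shuffled.closeness):
            assert c == pytest.approx(mapping[label], abs=1e-12)

    @given(scale=st.floats(min_value=0.01, max_value=100.0),
           column=st.integers(min_value=0, max_value=4))
    @settings(max_examples=30, deadline=None)
    def test_closeness_invariant_under_column_scaling(self, scale, column):
        """Vector normalisation removes per-criterion scale."""
        records = synthetic_data.gen_condition_table(seed=3)
        base = topsis.run_topsis(records)
        matrix = topsis.build_decision_matrix(records)
        values = matrix.values.copy()
        values[:, column] *= scale
        scaled = topsis.DecisionMatrix(
            alternative_labels=matrix.alternative_labels,
            criteria=matrix.criteria, values=values,
            directions=matrix.directions, weights=matrix.weights,
        )
        z = topsis.normalize(scaled)
        u = topsis.apply_weights(z, scaled.weights)
        dp, dn = topsis.separation_distances(
            u, topsis.ideal_solutions(u, scaled.directions)
        )
        c = topsis.closeness(dp, dn)
        np.testing.assert_allclose(c, base.closeness, atol=1e-9)


class TestValidation:
    def test_reported_table_passes_at_default_tolerance(self, closeness_table):
        report = topsis.validate_closeness_table(closeness_table, tolerance=0.001)
        assert report.all_pass
        assert report.rank_order_ok
        assert len(report.rows) == 30

    def test_perturbed_row_is_flagged(self, closeness_table):
        bad = closeness_table.copy()
        bad.loc[0, "c"] = 0.9
        report = topsis.validate_closeness_table(bad, tolerance=0.001)
        assert not report.all_pass
        assert report.failures[0].index == 0

    def test_exact_synthetic_rows_pass_at_tiny_tolerance(self, condition_records):
        result = topsis.run_topsis(condition_records)
        table = result.to_frame().rename(columns={"closeness": "c"})
        report = topsis.validate_closeness_table(table, tolerance=1e-12)
        assert report.all_pass
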