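"""GRA-TOPSIS fusion and the comparator rankings."""

import numpy as np
import pandas as pd
import pytest

from medequip import ranking
from medequip.core import (
    DecisionMatrix,
    IndicatorDefinition,
    ValidationError,
    WeightVector,
)


def make_matrix(arr, directions=None):
    arr = np.asarray(arr, dtype=float)
    cols = [f"C{i}" for i in range(arr.shape[1])]
    defs = [IndicatorDefinition(c, direction=(directions or {}).get(c, "benefit"))
            for c in cols]
    return DecisionMatrix(
        values=pd.DataFrame(arr, columns=cols,
                            index=[f"E{i}" for i in range(arr.shape[0])]),
        indicator_defs=defs,
    )


def make_weights(w, matrix):
    return WeightVector(matrix.indicator_ids, np.asarray(w, float), "test")


class TestWeightedMatrix:
    def test_equal_weights_scale_normalized_matrix(self):
        m = make_matrix([[1, 10], [2, 20], [3, 30]])
        w = make_weights([0.5, 0.5], m)
        S = ranking.weighted_normalized_matrix(m, w)
        np.testing.assert_allclose(S.to_numpy(),
                                   [[0, 0], [0.25, 0.25], [0.5, 0.5]])

    def test_column_maxima_equal_weights(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.uniform(1, 9, (6, 4)))
        w = make_weights(np.array([0.1, 0.2, 0.3, 0.4]), m)
        S = ranking.weighted_normalized_matrix(m, w)
        np.testing.assert_allclose(S.max(axis=0), w.weights)

    def test_dominating_row_equals_weight_vector(self):
        m = make_matrix([[9, 9, 9], [1, 2, 3], [4, 5, 6]])
        w = make_weights([0.2, 0.3, 0.5], m)
        S = ranking.weighted_normalized_matrix(m, w)
        np.testing.assert_allclose(S.iloc[0], w.weights)


class TestDistances:
    def test_ideal_row_has_zero_positive_distance(self):
        S = np.array([[0.2, 0.3], [0.1, 0.1], [0.2, 0.2]])
        d_pos, d_neg = ranking.euclidean_distances(S)
        assert d_pos[0] == pytest.approx(0.0)
        assert d_neg[1] == pytest.approx(0.0)

    def test_two_extreme_rows_are_weight_norm_apart(self):
        w = np.array([0.4, 0.6])
        S = np.array([w, [0.0, 0.0]])
        d_pos, d_neg = ranking.euclidean_distances(S)
        assert d_pos[1] == pytest.approx(np.linalg.norm(w))
        assert d_neg[0] == pytest.approx(np.linalg.norm(w))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        S = rng.uniform(size=(5, 3))
        d_pos, _ = ranking.euclidean_distances(S)
        direct = np.sqrt(((S - S.max(axis=0)) ** 2).sum(axis=1))
        np.testing.assert_allclose(d_pos, direct)


class TestGrayCoefficients:
    def test_ideal_entries_get_coefficient_one(self):
        S = np.array([[0.5, 0.2], [0.1, 0.4]])
        H_pos, _ = ranking.gray_coefficients(S)
        # each column max is an ideal entry with Delta=0, and Delta_min=0
        assert H_pos[0, 0] == pytest.approx(1.0)
        assert H_pos[1, 1] == pytest.approx(1.0)

    def test_lower_bound_one_third_at_default_resolution(self):
        rng = np.random.default_rng(9)
        S = rng.uniform(size=(6, 5))
        H_pos, H_neg = ranking.gray_coefficients(S, rho=0.5)
        for H in (H_pos, H_neg):
            assert H.min() >= 1 / 3 - 1e-12
            assert H.max() <= 1.0 + 1e-12

    def test_maximal_deviation_hits_lower_bound(self):
        S = np.array([[1.0, 1.0], [0.0, 0.0]])
        H_pos, _ = ranking.gray_coefficients(S, rho=0.5)
        assert H_pos[1, 0] == pytest.approx(1 / 3)

    def test_identical_rows_warn_and_return_ones(self):
        with pytest.warns(UserWarning, match="identical"):
            H_pos, H_neg = ranking.gray_coefficients(np.ones((3, 2)))
        np.testing.assert_allclose(H_pos, 1.0)

    def test_resolution_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ranking.gray_coefficients(np.eye(2), rho=0.0)


class TestGrayDegrees:
    def test_all_one_coefficients_give_unit_degree(self):
        H = np.ones((3, 4))
        w = np.full(4, 0.25)
        l_pos, l_neg = ranking.gray_degrees(H, H, w)
        np.testing.assert_allclose(l_pos, 1.0)

    def test_uniform_scheme_is_row_mean(self):
        rng = np.random.default_rng(2)
        H = rng.uniform(1 / 3, 1, (4, 5))
        l_pos, _ = ranking.gray_degrees(H, H, np.full(5, 0.2), scheme="uniform")
        np.testing.assert_allclose(l_pos, H.mean(axis=1))

    def test_degree_within_coefficient_range(self):
        rng = np.random.default_rng(3)
        H = rng.uniform(1 / 3, 1, (4, 6))
        w = rng.dirichlet(np.ones(6))
        l_pos, _ = ranking.gray_degrees(H, H, w)
        assert np.all(l_pos >= H.min(axis=1) - 1e-12)
        assert np.all(l_pos <= H.max(axis=1) + 1e-12)


class TestNormalizeMeasures:
    def test_case_study_measures_each_peak_at_one(self, case_study):
        fm = case_study.fusion_measures
        for col in fm.columns:
            out, = ranking.normalize_measures(fm[col].to_numpy())
            assert out.max() == pytest.approx(1.0)

    def test_constant_vector_maps_to_ones(self):
        out, = ranking.normalize_measures(np.full(4, 0.7))
        np.testing.assert_allclose(out, 1.0)

    def test_scale_invariance(self):
        v = np.array([1.0, 2.0, 4.0])
        a, = ranking.normalize_measures(v)
        b, = ranking.normalize_measures(5.0 * v)
        np.testing.assert_allclose(a, b)

    def test_zero_maximum_rejected(self):
        with pytest.raises(ValidationError):
            ranking.normalize_measures(np.zeros(3))


class TestFuse:
    def test_case_study_decision_factors(self, case_study):
        """The published normalized measures yield the published fusion
        scores for all four scanners at 3 decimals."""
        fm = case_study.fusion_measures
        xi, _, _ = ranking.fuse(fm["D_pos"].to_numpy(), fm["D_neg"].to_numpy(),
                                fm["L_pos"].to_numpy(), fm["L_neg"].to_numpy())
        np.testing.assert_allclose(
            np.round(xi, 3),
            case_study.method_scores["GRA-TOPSIS"].to_numpy(),
        )

    def test_balanced_measures_give_half(self):
        D = np.array([0.6, 0.8])
        L = np.array([0.9, 0.5])
        for orientation in ("priority", "proximity"):
            xi, _, _ = ranking.fuse(D, D, L, L, orientation=orientation)
            np.testing.assert_allclose(xi, 0.5)

    def test_orientation_duality(self):
        rng = np.random.default_rng(6)
        D_pos, D_neg, L_pos, L_neg = rng.uniform(0.1, 1.0, (4, 5))
        xi_p, _, _ = ranking.fuse(D_pos, D_neg, L_pos, L_neg,
                                  orientation="priority")
        xi_x, _, _ = ranking.fuse(D_pos, D_neg, L_pos, L_neg,
                                  orientation="proximity")
        np.testing.assert_allclose(xi_p + xi_x, 1.0)

    def test_preference_must_be_convex(self):
        v = np.array([0.5, 0.6])
        with pytest.raises(ValidationError):
            ranking.fuse(v, v, v, v, alpha1=0.7, alpha2=0.5)


class TestFullFusionRanking:
    def test_weight_rescaling_invariance(self, small_matrix, equal_weights):
        """xi is unchanged if the weights arrive pre-scaled by a positive
        constant and renormalized (i.e. it depends only on the direction of
        the weight vector)."""
        r1 = ranking.rank_gra_topsis(small_matrix, equal_weights)
        w2 = WeightVector(equal_weights.indicator_ids,
                          np.array([2.0, 2.0, 2.0]) / 6.0, "test")
        r2 = ranking.rank_gra_topsis(small_matrix, w2)
        np.testing.assert_allclose(r1.scores, r2.scores)

    def test_dominated_equipment_replaced_first(self):
        """If B is weakly worse than A on every direction-adjusted
        criterion (strictly on one), B's xi exceeds A's."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            base = rng.uniform(1, 9, (4, 3))
            base[1] = base[0] - rng.uniform(0.2, 0.8, 3)  # B dominated by A
            m = make_matrix(base, directions={"C2": "cost"})
            # cost direction: B must have larger raw value to be worse
            m.values.iloc[1, 2] = m.values.iloc[0, 2] + 1.0
            w = rng.dirichlet(np.ones(3))
            res = ranking.rank_gra_topsis(m, make_weights(w, m))
            assert res.scores[1] > res.scores[0]

    def test_tied_rows_share_average_rank(self, equal_weights):
        m = make_matrix([[1, 2, 3], [1, 2, 3], [5, 6, 1]])
        w = make_weights(np.full(3, 1 / 3), m)
        res = ranking.rank_gra_topsis(m, w)
        assert res.ranks[0] == res.ranks[1]
        assert res.ranks[0] in (1.5, 2.5)


class TestPlainComparators:
    def test_single_criterion_order_follows_direction(self):
        m = make_matrix([[1, 1.0], [2, 1.1], [3, 1.2]],
                        directions={"C0": "benefit", "C1": "benefit"})
        w = make_weights([0.99, 0.01], m)
        gra = ranking.rank_gra(m, w)
        top = ranking.rank_topsis(m, w)
        # row 0 is worst on the dominant criterion: replace first
        assert gra.ranks[0] == 1 and top.ranks[0] == 1
        assert gra.ranks[2] == 3 and top.ranks[2] == 3

    def test_topsis_matches_direct_formula(self):
        rng = np.random.default_rng(21)
        m = make_matrix(rng.uniform(1, 9, (6, 4)))
        w = make_weights(rng.dirichlet(np.ones(4)), m)
        res = ranking.rank_topsis(m, w)
        S = ranking.weighted_normalized_matrix(m, w).to_numpy()
        d_pos = np.sqrt(((S - S.max(axis=0)) ** 2).sum(axis=1))
        d_neg = np.sqrt(((S - S.min(axis=0)) ** 2).sum(axis=1))
        np.testing.assert_allclose(res.scores, d_pos / (d_pos + d_neg))

    def test_identical_rows_tie(self):
        m = make_matrix([[1, 2], [1, 2], [3, 4]])
        w = make_weights([0.5, 0.5], m)
        res = ranking.rank_gra(m, w)
        assert res.ranks[0] == res.ranks[1]


class TestVikor:
    def test_worst_equipment_gets_q_zero(self):
        m = make_matrix([[1, 9], [5, 5], [9, 1.0]],
                        directions={"C1": "cost"})
        # row 0: worst on both direction-adjusted criteria -> replace first
        w = make_weights([0.5, 0.5], m)
        res = ranking.rank_vikor(m, w)
        assert res.scores[0] == pytest.approx(0.0)
        assert res.ranks[0] == 1

    def test_best_equipment_gets_q_one(self):
        m = make_matrix([[1, 9], [5, 5], [9, 1.0]], directions={"C1": "cost"})
        res = ranking.rank_vikor(m, make_weights([0.5, 0.5], m))
        assert res.scores[2] == pytest.approx(1.0)
        assert res.ranks[2] == 3

    def test_hand_computed_three_by_two(self):
        """3x2 benefit matrix, weights (0.6, 0.4), v=0.5.

        z columns: (0, .5, 1) each, so replacement need u = 1 - z has rows
        (1,1), (.5,.5), (0,0); row 0 is the neediest (u = best level).
        S = (0, .5, 1); R = (0, .3, .6); Q = (0, .5, 1); ranks (1, 2, 3).
        """
        m = make_matrix([[1, 10], [2, 20], [3, 30]])
        res = ranking.rank_vikor(m, make_weights([0.6, 0.4], m), v=0.5)
        np.testing.assert_allclose(res.diagnostics["S"], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(res.diagnostics["R"], [0.0, 0.3, 0.6])
        np.testing.assert_allclose(res.scores, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(res.ranks, [1, 2, 3])

    def test_vikor_and_fusion_agree_on_dominated_pairs(self):
        """VIKOR and the fusion method both replace a dominated device
        before the device that dominates it."""
        rng = np.random.default_rng(33)
        for _ in range(5):
            base = rng.uniform(2, 9, (4, 3))
            base[1] = base[0] - rng.uniform(0.3, 1.0, 3)
            m = make_matrix(base)
            w = make_weights(rng.dirichlet(np.ones(3)), m)
            vik = ranking.rank_vikor(m, w)
            fus = ranking.rank_gra_topsis(m, w)
            assert vik.ranks[1] < vik.ranks[0]
            assert fus.ranks[1] < fus.ranks[0]
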