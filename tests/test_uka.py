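"""Upstream kinase analysis: tau, Q-scores, permutation nulls, ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinact import (
    KinaseSubstrateSets,
    kinase_statistic,
    peptide_effect,
    q_from_counts,
    rank_kinases,
    significance_score,
    specificity_score,
)
from kinact.uka import standardized_delta
from tests.conftest import make_matrix


class TestQFromCounts:
    @pytest.mark.parametrize("M", [1, 10, 500])
    def test_closed_form_and_bounds(self, M):
        for m in range(M + 1):
            q = q_from_counts(m, M)
            assert q == pytest.approx(-10 * math.log10(max(m / M, 1 / M)), abs=0)
            assert 0.0 <= q <= 10 * math.log10(M) + 1e-12

    def test_reference_values(self):
        assert q_from_counts(500, 500) == 0.0
        assert q_from_counts(0, 500) == pytest.approx(26.9897, abs=1e-4)
        assert q_from_counts(25, 500) == pytest.approx(13.0103, abs=1e-4)

    def test_monotone_nonincreasing_in_m(self):
        qs = [q_from_counts(m, 100) for m in range(101)]
        assert all(a >= b for a, b in zip(qs, qs[1:]))

    @pytest.mark.parametrize("m, M", [(5, 4), (-1, 10), (0, 0)])
    def test_domain_errors(self, m, M):
        with pytest.raises(ValueError):
            q_from_counts(m, M)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(1, 5000).flatmap(lambda M: st.tuples(st.just(M), st.integers(0, M))))
    def test_bounds_hold_for_any_counts(self, mM):
        M, m = mM
        q = q_from_counts(m, M)
        assert 0.0 <= q <= 10 * math.log10(M) + 1e-12
        assert q == pytest.approx(-10 * math.log10(max(m / M, 1 / M)))


class TestPeptideEffect:
    def test_matches_hand_computed_standardized_difference(self, toy_annotation):
        neg, pos = [5.0, 6.0, 7.0], [3.0, 3.5, 4.0]
        matrix = make_matrix([neg + pos])
        delta = peptide_effect(matrix, toy_annotation)
        pooled = math.sqrt(((2) * np.var(neg, ddof=1) + (2) * np.var(pos, ddof=1)) / 4)
        assert delta.iloc[0] == pytest.approx((np.mean(neg) - np.mean(pos)) / pooled)

    def test_identical_group_means_give_zero(self, toy_annotation):
        matrix = make_matrix([[5.0, 6.0, 7.0, 5.0, 6.0, 7.0]])
        assert peptide_effect(matrix, toy_annotation).iloc[0] == pytest.approx(0.0)

    def test_zero_variance_substrate_excluded(self, toy_annotation):
        matrix = make_matrix([[2.0, 2.0, 2.0, 1.0, 1.0, 1.0], [5, 6, 7, 3, 3.5, 4]])
        delta = peptide_effect(matrix, toy_annotation)
        assert list(delta.index) == [matrix.index[1]]

    def test_sign_positive_when_negative_group_higher(self, toy_annotation):
        matrix = make_matrix([[9.0, 9.5, 8.5, 4.0, 4.5, 3.5]])
        assert peptide_effect(matrix, toy_annotation).iloc[0] > 0


class TestKinaseStatistic:
    def test_single_substrate(self):
        delta = pd.Series({"a": 1.5, "b": -2.0})
        assert kinase_statistic(delta, ["a"]) == 1.5

    def test_uniform_mean(self):
        delta = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        assert kinase_statistic(delta, ["a", "b", "c"]) == pytest.approx(2.0)

    def test_all_zero(self):
        delta = pd.Series({"a": 0.0, "b": 0.0})
        assert kinase_statistic(delta, ["a", "b"]) == 0.0

    def test_prediction_weights(self):
        delta = pd.Series({"a": 1.0, "b": 3.0})
        tau = kinase_statistic(delta, ["a", "b"], weights=np.array([3.0, 1.0]))
        assert tau == pytest.approx(1.5)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            kinase_statistic(pd.Series({"a": 1.0}), ["zzz"])


def brute_force_significance(matrix, annot, members):
    """Exhaustive sample-label permutation count, independent of the
    library's permutation machinery."""
    X = matrix.to_numpy(dtype=float)
    n = X.shape[1]
    n_neg = int((annot["pr"] == "neg").sum())
    obs_mask = (annot["pr"] == "neg").to_numpy()
    obs_delta = standardized_delta(X, obs_mask)
    idx = [matrix.index.get_loc(s) for s in members]
    tau = np.nanmean(obs_delta[idx])
    count = total = 0
    for combo in itertools.combinations(range(n), n_neg):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        d = standardized_delta(X, mask)
        tau_p = np.nanmean(d[idx])
        total += 1
        if abs(tau_p) > abs(tau):
            count += 1
    return tau, count, total


class TestSignificanceScore:
    def test_equals_exhaustive_enumeration(self, toy_annotation):
        rng = np.random.default_rng(7)
        matrix = make_matrix(rng.normal(7, 1, size=(10, 6)))
        members = list(matrix.index[:4])
        tau, m_sig, q_sig = significance_score(matrix, toy_annotation, members, M=100, seed=1)
        tau_bf, m_bf, total = brute_force_significance(matrix, toy_annotation, members)
        assert total == 20  # C(6,3) label splits, enumerated not sampled
        assert tau == pytest.approx(tau_bf)
        assert m_sig == m_bf
        assert q_sig == pytest.approx(q_from_counts(m_bf, 20))

    def test_planted_shift_reaches_score_cap(self):
        rng = np.random.default_rng(12)
        annot = pd.DataFrame(
            {"pr": ["neg"] * 5 + ["pos"] * 5, "her2": ["neg"] * 10},
            index=[f"S{i}" for i in range(10)],
        )
        values = rng.normal(7, 0.5, size=(20, 10))
        values[:6, :5] += 5.0  # very strong PR- shift on the set's substrates
        matrix = make_matrix(values, samples=list(annot.index))
        members = list(matrix.index[:6])
        _, m_sig, q_sig = significance_score(matrix, annot, members, M=100, seed=3)
        assert m_sig == 0
        assert q_sig == pytest.approx(10 * math.log10(100))

    def test_null_exceedance_fraction_near_half(self):
        """With tau itself drawn from the null, the strict-exceedance
        fraction m/M averages ~0.5 across simulated datasets."""
        rng = np.random.default_rng(99)
        fracs = []
        for _ in range(100):
            annot = pd.DataFrame(
                {"pr": ["neg"] * 4 + ["pos"] * 4, "her2": ["neg"] * 8},
                index=[f"S{i}" for i in range(8)],
            )
            matrix = make_matrix(
                rng.normal(7, 1, size=(15, 8)), samples=list(annot.index)
            )
            _, m_sig, _ = significance_score(
                matrix, annot, list(matrix.index[:5]), M=70, seed=int(rng.integers(2**31))
            )
            fracs.append(m_sig / 70)
        assert abs(np.mean(fracs) - 0.5) <= 0.1

    def test_degenerate_grouping_rejected(self, toy_annotation):
        matrix = make_matrix(np.ones((3, 6)))
        annot = toy_annotation.copy()
        annot["pr"] = "pos"
        with pytest.raises(ValueError):
            significance_score(matrix, annot, list(matrix.index[:2]), M=10, seed=0)


class TestSpecificityScore:
    def test_equals_exhaustive_enumeration(self):
        delta = pd.Series({"a": 1.2, "b": -0.3, "c": 0.8, "d": -1.5})
        members = ["a", "c"]
        m_spec, q_spec = specificity_score(delta, members, list(delta.index), M=50, seed=0)
        tau = abs(delta[members].mean())
        count = sum(
            1
            for combo in itertools.combinations(delta.index, 2)
            if abs(delta[list(combo)].mean()) > tau
        )
        assert m_spec == count
        assert q_spec == pytest.approx(q_from_counts(count, 6))

    def test_unspecific_set_scores_near_zero(self):
        rng = np.random.default_rng(21)
        values = np.concatenate([rng.normal(0, 1, 99), [0.0]])
        delta = pd.Series(values, index=[f"p{i}" for i in range(100)])
        # a set sitting exactly at the universe mean of a symmetric delta
        members = ["p99"]
        # C(100, 1) = 100 <= M, so the null is enumerated exhaustively
        m_spec, q_spec = specificity_score(delta, members, list(delta.index), M=400, seed=2)
        assert m_spec / 100 > 0.8  # nearly every random substrate beats it
        assert q_spec <= 1.0

    def test_set_covering_universe_rejected(self):
        delta = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            specificity_score(delta, ["a", "b"], ["a", "b"], M=10, seed=0)


class TestRankKinases:
    def test_single_kinase_gets_rank_one(self, collapsed_matrix):
        matrix, annot, _ = collapsed_matrix
        sets = KinaseSubstrateSets(
            sets={"ONLY": list(matrix.index[:4])}, universe=list(matrix.index)
        )
        scores = rank_kinases(matrix, annot, sets, M=50, seed=0)
        assert list(scores["rank"]) == [1]

    def test_invariant_to_set_supply_order(self, collapsed_matrix):
        matrix, annot, truth = collapsed_matrix
        sets = truth["ks_map"]
        reversed_sets = KinaseSubstrateSets(
            sets=dict(reversed(list(sets.sets.items()))), universe=sets.universe
        )
        a = rank_kinases(matrix, annot, sets, M=100, seed=5)
        b = rank_kinases(matrix, annot, reversed_sets, M=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_sets_tie_broken_by_name(self, collapsed_matrix):
        matrix, annot, _ = collapsed_matrix
        members = list(matrix.index[:5])
        sets = KinaseSubstrateSets(
            sets={"ZZZ": members, "AAA": members}, universe=list(matrix.index)
        )
        scores = rank_kinases(matrix, annot, sets, M=50, seed=1)
        assert scores["tau"].nunique() == 1
        assert list(scores["kinase"]) == ["AAA", "ZZZ"]

    def test_planted_driver_ranks_first(self, collapsed_matrix):
        matrix, annot, truth = collapsed_matrix
        scores = rank_kinases(matrix, annot, truth["ks_map"], M=200, seed=7)
        assert scores.loc[0, "kinase"] == "DRV1"
        assert scores.loc[0, "tau"] > 0  # driver is up in PR-

    def test_no_scoreable_kinase_rejected(self, collapsed_matrix):
        matrix, annot, _ = collapsed_matrix
        sets = KinaseSubstrateSets(
            sets={"GHOST": ["missing_1_13"]}, universe=list(matrix.index) + ["missing_1_13"]
        )
        with pytest.raises(ValueError):
            rank_kinases(matrix, annot, sets, M=20, seed=0)


class TestKinaseSubstrateSets:
    def test_members_must_be_in_universe(self):
        with pytest.raises(ValueError):
            KinaseSubstrateSets(sets={"K": ["x"]}, universe=["y"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            KinaseSubstrateSets(sets={"K": []}, universe=["x"])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            KinaseSubstrateSets(
                sets={"K": ["x"]}, universe=["x"], weights={("K", "x"): 0.0}
            )
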