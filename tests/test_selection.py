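import math

import numpy as np
import pytest
from scipy import stats

from oracles import exhaustive_permutation_p, pooled_t
from pspnet.datatypes import DetectionProfile, FeatureSet, SignatureMatrix
from pspnet.selection import (
    balanced_masks,
    bh_adjust,
    permutation_pvalue,
    rank_score,
    rank_score_sum,
    select_features,
    t_matrix,
    t_statistic,
)


class TestTStatistic:
    def test_zero_variance_sentinels(self):
        assert t_statistic([1, 1], [0, 0]) == math.inf
        assert t_statistic([0, 0], [1, 1]) == -math.inf
        assert t_statistic([0.2, 0.4, 0.6], [0.2, 0.4, 0.6]) == 0.0

    def test_matches_textbook_formula_and_scipy(self):
        ha = [0.8, 0.6, 0.7, 0.9]
        hb = [0.3, 0.2, 0.4]
        t = t_statistic(ha, hb)
        assert t == pytest.approx(pooled_t(ha, hb))
        assert t == pytest.approx(stats.ttest_ind(ha, hb, equal_var=True).statistic)

    def test_vectorised_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        x = rng.random((9, 7))
        masks, _ = balanced_masks(9, 4, 1000)
        t = t_matrix(x, masks)
        for i in [0, 10, 50, len(masks) - 1]:
            a = x[masks[i]]
            b = x[~masks[i]]
            for j in range(7):
                assert t[i, j] == pytest.approx(t_statistic(a[:, j], b[:, j]))


class TestPermutationP:
    @pytest.mark.parametrize("sizes", [(2, 2), (3, 3)])
    @pytest.mark.parametrize("alternative,tie_policy,pseudocount", [
        ("signed", "strict", False),
        ("signed", "strict", True),
        ("two-sided", "mid", False),
    ])
    def test_exhaustive_equals_brute_force(self, sizes, alternative,
                                           tie_policy, pseudocount):
        rng = np.random.default_rng(1234)
        labels = ["A"] * sizes[0] + ["B"] * sizes[1]
        for _ in range(50):
            col = rng.integers(0, 5, size=len(labels)) / 4.0  # tied, discrete
            p = permutation_pvalue(col, labels, n_perm=10000,
                                   alternative=alternative,
                                   pseudocount=pseudocount,
                                   tie_policy=tie_policy)
            expect = exhaustive_permutation_p(list(col), labels,
                                              alternative=alternative,
                                              pseudocount=pseudocount,
                                              tie_policy=tie_policy)
            assert p == pytest.approx(expect, abs=1e-12)

    def test_constant_feature_strict_rule_gives_zero(self):
        labels = ["A"] * 3 + ["B"] * 3
        p = permutation_pvalue([0.5] * 6, labels)
        assert p == 0.0  # all null t equal the observed 0: degeneracy of strict rule

    def test_infinite_t_unreachable_null(self):
        # zero pooled variance with different means: +inf sentinel, p = 0
        labels = ["A", "A", "B", "B"]
        p = permutation_pvalue([1.0, 1.0, 0.0, 0.0], labels)
        assert p == 0.0

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(5)
        labels = ["A"] * 7 + ["B"] * 7  # C(14,7)=3432 > n_perm forces MC
        col = rng.random(14)
        exact = exhaustive_permutation_p(list(col), labels)
        approx = permutation_pvalue(col, labels, n_perm=3000, seed=0)
        assert approx == pytest.approx(exact, abs=0.03)

    def test_signed_rule_size_is_twice_alpha_on_continuous_null(self):
        """The sign-adaptive single tail rejects ~2*alpha under the null;
        the two-sided mid-p convention restores ~alpha (see docs)."""
        rng = np.random.default_rng(99)
        x = rng.normal(size=(12, 1500))
        masks, _ = balanced_masks(12, 6, 10**9)
        t = t_matrix(x, masks)
        t_obs = t[0]  # first enumerated mask as the "true" labelling
        b_hi = (t > t_obs[None, :]).sum(axis=0)
        b_lo = (t < t_obs[None, :]).sum(axis=0)
        b = np.where(t_obs < 0, b_lo, b_hi)
        p_signed = b / len(masks)
        p_two = np.minimum(1, 2 * (b + 0.5) / len(masks))
        assert (p_signed <= 0.05).mean() == pytest.approx(0.10, abs=0.02)
        assert (p_two <= 0.05).mean() == pytest.approx(0.05, abs=0.015)


class TestBH:
    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_and_singleton(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_adjust([0.7]) == pytest.approx([0.7])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRankScore:
    def _feature(self):
        return FeatureSet("F", {"A", "B", "C", "D"})

    def test_worked_sum(self):
        # A reported by 4 patients (1.1, 0.8, 1, 1.2); B by 1 patient (5)
        profiles = [
            DetectionProfile("p1", "mod", {"A", "B"}, {"A": 1.1, "B": 5.0}),
            DetectionProfile("p2", "mod", {"A"}, {"A": 0.8}),
            DetectionProfile("p3", "mod", {"A"}, {"A": 1.0}),
            DetectionProfile("p4", "mod", {"A"}, {"A": 1.2}),
        ]
        s, u = rank_score_sum(self._feature(), profiles)
        assert s == pytest.approx(0.1 + (1 / 0.8 - 1) + 0 + 0.2 + 4)
        assert u == 2
        assert rank_score(self._feature(), profiles) == pytest.approx(s / 2)

    def test_normalisation_uses_unique_reported_not_size(self):
        profiles = [
            DetectionProfile("p1", "mod", {"A"}, {"A": 1.1}),
            DetectionProfile("p2", "mod", {"A", "B"}, {"A": 1.2, "B": 5.0}),
        ]
        score = rank_score(self._feature(), profiles)
        assert score == pytest.approx((0.1 + 0.2 + 4) / 2)

    def test_no_reports_scores_zero(self):
        profiles = [DetectionProfile("p1", "mod", {"X"}, {"X": 2.0})]
        assert rank_score(self._feature(), profiles) == 0.0

    def test_reciprocal_ratios_contribute_identically(self):
        for r in (1.5, 3.0, 10.0):
            a = [DetectionProfile("p1", "mod", {"A"}, {"A": r})]
            b = [DetectionProfile("p1", "mod", {"A"}, {"A": 1 / r})]
            assert rank_score(self._feature(), a) == pytest.approx(
                rank_score(self._feature(), b))

    def test_patient_order_invariance(self):
        profiles = [
            DetectionProfile("p1", "mod", {"A"}, {"A": 1.4}),
            DetectionProfile("p2", "mod", {"B"}, {"B": 0.5}),
            DetectionProfile("p3", "mod", {"C"}, {"C": 2.0}),
        ]
        f = self._feature()
        assert rank_score(f, profiles) == rank_score(f, profiles[::-1])

    def test_mixed_classes_rejected(self):
        profiles = [
            DetectionProfile("p1", "mod", {"A"}, {"A": 1.4}),
            DetectionProfile("p2", "poor", {"B"}, {"B": 2.0}),
        ]
        with pytest.raises(ValueError, match="multiple classes"):
            rank_score(self._feature(), profiles)


class TestSelectFeatures:
    def _matrix(self, seed=0, n_a=4, n_b=4, n_feat=6):
        import pandas as pd

        rng = np.random.default_rng(seed)
        pids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=pids)
        vals = pd.DataFrame(rng.random((n_a + n_b, n_feat)), index=pids,
                            columns=[f"f{j}" for j in range(n_feat)])
        return SignatureMatrix(vals, labels)

    def test_pvalues_match_per_feature_op_in_exhaustive_mode(self):
        m = self._matrix()
        table = select_features(m, n_perm=1000)
        for j, fid in enumerate(m.feature_ids):
            p = permutation_pvalue(m.values[fid].to_numpy(), list(m.class_labels),
                                   n_perm=1000)
            assert table.loc[j, "p_perm"] == pytest.approx(p)

    def test_constant_feature_flagged(self):
        m = self._matrix()
        m.values["f0"] = 0.25
        table = select_features(m, n_perm=500).set_index("feature_id")
        assert bool(table.loc["f0", "constant"])

    def test_monte_carlo_reproducible_given_seed(self):
        m = self._matrix(n_a=7, n_b=7, n_feat=4)
        t1 = select_features(m, n_perm=500, seed=11)
        t2 = select_features(m, n_perm=500, seed=11)
        assert (t1["p_perm"] == t2["p_perm"]).all()
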