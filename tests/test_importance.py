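"""Feature-importance aggregation, filtering, and scoring against ground truth."""

import numpy as np
import pytest

from gsbench.importance import (aggregate_across_folds, effect_importance_correlation,
                                relative_filter, score_against_truth, top_k_select)
from gsbench.simulate import GroundTruth


def make_truth(causal, beta, background, gamma):
    return GroundTruth(
        background_indices=np.asarray(background), gamma=np.asarray(gamma, dtype=float),
        causal_indices=np.asarray(causal), beta=np.asarray(beta, dtype=float),
        interaction=None, u=np.zeros(2), epsilon=np.zeros(2), sigma2=1.0,
        sample_indices=np.arange(2), x_fixed=np.zeros((2, len(causal))),
    )


class TestTopK:
    def test_short_vector_returned_whole_nonzero_first(self):
        v = np.zeros(10)
        v[[2, 5, 8]] = [3.0, -1.0, 2.0]
        sel = top_k_select(v, k=1000)
        assert len(sel) == 10
        assert sel[:3].tolist() == [2, 8, 5]

    def test_k_one_picks_max_magnitude(self):
        assert top_k_select(np.array([0.5, -4.0, 3.0]), k=1).tolist() == [1]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=200)
        sel = top_k_select(v, k=50)
        oracle = sorted(range(200), key=lambda j: (-abs(v[j]), j))[:50]
        assert sel.tolist() == oracle


class TestAggregation:
    def test_single_fold_min_max_normalization(self):
        avg = aggregate_across_folds([np.array([2.0, 1.0, 0.0])], k=1000)
        assert avg == {0: 1.0, 1: 0.5, 2: 0.0}

    def test_absent_folds_contribute_zero(self):
        folds = [np.array([0.9, 0.5, 0.0]),
                 np.array([0.0, 0.5, 0.9]),
                 np.array([0.0, 0.5, 0.9])]
        avg = aggregate_across_folds(folds, k=2)  # marker 0 only in fold 0's top-2
        assert avg[0] == pytest.approx(1.0 / 3.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        folds = [rng.normal(size=30) for _ in range(3)]
        k = 10
        avg = aggregate_across_folds(folds, k=k)
        # brute force: normalize each fold's top-k magnitudes, average with zeros
        expected = {}
        tops = []
        for v in folds:
            a = np.abs(v)
            top = sorted(range(30), key=lambda j: (-a[j], j))[:k]
            lo, hi = a[top].min(), a[top].max()
            tops.append({j: (a[j] - lo) / (hi - lo) for j in top})
        for j in set().union(*tops):
            expected[j] = sum(t.get(j, 0.0) for t in tops) / 3
        assert set(avg) == set(expected)
        for j in avg:
            assert avg[j] == pytest.approx(expected[j])

    def test_values_stay_in_unit_interval(self):
        rng = np.random.default_rng(2)
        avg = aggregate_across_folds([rng.normal(size=50) for _ in range(4)], k=20)
        assert all(0.0 <= v <= 1.0 for v in avg.values())

    def test_constant_fold_warns_and_contributes_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            avg = aggregate_across_folds([np.full(5, 2.0)], k=5)
        assert all(v == 0.0 for v in avg.values())


class TestRelativeFilter:
    def test_one_percent_cut(self):
        kept = relative_filter({0: 1.0, 1: 0.5, 2: 0.009}, fraction=0.01)
        assert set(kept) == {0, 1}

    def test_all_equal_values_retained(self):
        kept = relative_filter({0: 0.3, 1: 0.3, 2: 0.3}, fraction=0.01)
        assert len(kept) == 3

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(3)
        mapping = {j: float(v) for j, v in enumerate(rng.random(40))}
        sizes = [len(relative_filter(mapping, f)) for f in (0.01, 0.1, 0.3, 0.7)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_input(self):
        assert relative_filter({}, 0.01) == {}


class TestScoring:
    def test_tpr_counts_background_within_important(self):
        truth = make_truth([9], [1.0], [0, 1], [0.1, 0.2])
        avg = {0: 0.5, 1: 0.4, 3: 0.3, 4: 0.2, 9: 1.0}
        rep = score_against_truth(avg, truth)
        assert rep.n_important == 5
        assert rep.background_found == 2
        assert rep.tpr == pytest.approx(0.4)
        assert rep.causal_found == 1 and rep.causal_ranks == [1]

    def test_zero_causal_degenerate(self):
        truth = make_truth([], [], [0], [0.1])
        rep = score_against_truth({0: 1.0}, truth)
        assert rep.causal_total == 0 and rep.causal_found == 0
        assert rep.causal_ranks == []

    def test_filtered_counts_never_exceed_unfiltered(self):
        truth = make_truth([2], [1.0], [0, 1], [0.1, 0.2])
        avg = {0: 1.0, 1: 0.005, 2: 0.8}
        rep = score_against_truth(avg, truth)
        assert rep.n_important_filtered <= rep.n_important
        assert rep.background_found_filtered <= rep.background_found


class TestEffectCorrelation:
    def make(self, n=30, seed=4):
        rng = np.random.default_rng(seed)
        gamma = rng.normal(0, 0.1, size=n)
        return make_truth([], [], list(range(n)), gamma), np.abs(gamma)

    def test_proportional_importances_give_unit_correlation(self):
        truth, eff = self.make()
        r, table = effect_importance_correlation(truth, {j: 3.0 * e for j, e in enumerate(eff)})
        assert r == pytest.approx(1.0)
        assert len(table) == (eff > 0).sum()

    def test_antiproportional_importances_give_minus_one(self):
        truth, eff = self.make()
        r, _ = effect_importance_correlation(
            truth, {j: float(1.0 - e) for j, e in enumerate(eff)})
        assert r == pytest.approx(-1.0, abs=1e-6)

    def test_permutation_null_centers_at_zero(self):
        truth, eff = self.make(n=50)
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(100):
            perm = rng.permutation(eff)
            r, _ = effect_importance_correlation(
                truth, {j: float(p) + 1e-9 for j, p in enumerate(perm)})
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_too_few_pairs_raise(self):
        truth = make_truth([], [], [0, 1], [0.1, 0.2])
        with pytest.raises(ValueError, match="need >= 3"):
            effect_importance_correlation(truth, {0: 0.5, 1: 0.5})
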