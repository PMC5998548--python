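import numpy as np
import pytest

import oracles
from toxpisim.evaluation import (
    SignificancePolicy,
    bartlett_variance_test,
    mean_rank_change,
    rmse,
    score_variance,
    summarize_combination,
    wilcoxon_paired,
    EvaluationRecord,
)


POLICY = SignificancePolicy(family_alpha=0.001, n_comparisons=252)


class TestRmse:
    def test_zero_iff_equal_and_symmetric(self):
        x = np.array([0.1, 0.5, 0.9])
        y = np.array([0.2, 0.4, 0.8])
        assert rmse(x, x) == 0.0
        assert rmse(x, y) == rmse(y, x) > 0

    def test_constant_shift_closed_form(self):
        x = np.linspace(0, 1, 7)
        assert rmse(x + 0.3, x) == pytest.approx(0.3)
        assert rmse(x - 0.3, x) == pytest.approx(0.3)

    def test_swapped_unit_vectors(self):
        assert rmse([0.0, 1.0], [1.0, 0.0]) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            rmse([1.0, 2.0], [1.0])


class TestMeanRankChange:
    def test_identical_ranks_give_zero(self):
        ranks = np.tile(np.arange(1, 6), (4, 1))
        signed, absolute = mean_rank_change(ranks, np.arange(1, 6))
        assert not signed.any() and not absolute.any()

    def test_single_replicate_signed_and_absolute(self):
        signed, absolute = mean_rank_change(np.array([[1, 2, 3]]), np.array([3, 2, 1]))
        assert signed.tolist() == [-2.0, 0.0, 2.0]
        assert absolute.tolist() == [2.0, 0.0, 2.0]

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(6)
        ranks = rng.integers(1, 11, size=(5, 10)).astype(float)
        ref = rng.permutation(np.arange(1, 11)).astype(float)
        signed, absolute = mean_rank_change(ranks, ref)
        for i in range(10):
            diffs = [ranks[r, i] - ref[i] for r in range(5)]
            assert signed[i] == pytest.approx(sum(diffs) / 5)
            assert absolute[i] == pytest.approx(sum(abs(d) for d in diffs) / 5)

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError):
            mean_rank_change(np.ones((2, 3)), np.ones(4))


class TestScoreVariance:
    def test_constant_replicates_zero_variance(self):
        assert not score_variance(np.ones((5, 4))).any()

    def test_two_point_sample_variance(self):
        # scores 0 and 1 across two replicates: var = ((0.5)^2 * 2) / (2 - 1)
        assert score_variance(np.array([[0.0], [1.0]]))[0] == pytest.approx(0.5)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(8)
        table = rng.random((7, 12))
        got = score_variance(table)
        for i in range(12):
            mean = sum(table[:, i]) / 7
            var = sum((v - mean) ** 2 for v in table[:, i]) / 6
            assert got[i] == pytest.approx(var)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            score_variance(np.ones((1, 3)))


class TestWilcoxon:
    def test_identical_vectors_not_significant(self):
        x = np.linspace(0, 1, 20)
        p, sig = wilcoxon_paired(x, x, POLICY)
        assert p == 1.0 and not sig

    def test_six_uniform_signs_exact_p(self):
        """All 6 differences positive: the most extreme of 2^6 sign
        assignments, two-sided exact p = 2/64."""
        ref = np.zeros(6)
        sim = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        p, _ = wilcoxon_paired(sim, ref, POLICY)
        assert p == pytest.approx(2 / 64)

    def test_exact_matches_enumeration_small_n(self):
        """Exact p agrees with full enumeration of sign assignments for n <= 10."""
        rng = np.random.default_rng(3)
        for n in (6, 8, 10):
            d = rng.uniform(0.1, 1, size=n) * rng.choice([-1, 1], size=n)
            p, _ = wilcoxon_paired(d, np.zeros(n), POLICY)
            ranks = np.argsort(np.argsort(np.abs(d))) + 1
            w_obs = ranks[d > 0].sum()
            stats = []
            for signs in range(2**n):
                w = sum(ranks[i] for i in range(n) if (signs >> i) & 1)
                stats.append(w)
            stats = np.array(stats)
            mu = stats.mean()
            p_exact = np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-12)
            assert p == pytest.approx(p_exact)

    def test_large_uniform_shift_highly_significant(self):
        rng = np.random.default_rng(1)
        ref = rng.random(426)
        p, sig = wilcoxon_paired(ref + 0.5, ref, POLICY)
        assert sig and p < 0.001 / 252


class TestBartlett:
    def test_permuted_identical_samples(self):
        rng = np.random.default_rng(5)
        x = rng.random(50)
        p, sig = bartlett_variance_test(x, rng.permutation(x), POLICY)
        assert p == pytest.approx(1.0) and not sig

    def test_matches_textbook_statistic(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, size=50)
        y = rng.normal(0, 2, size=50)
        p, _ = bartlett_variance_test(x, y, POLICY)
        _, p_oracle = oracles.bartlett_statistic(x, y)
        assert p == pytest.approx(p_oracle)

    def test_zero_variance_untestable(self):
        with pytest.raises(ValueError, match="untestable"):
            bartlett_variance_test(np.ones(5), np.array([1.0, 2.0, 3.0]), POLICY)


class TestSummarizeCombination:
    @staticmethod
    def record(rmse_value, rank_change=0.0):
        return EvaluationRecord(
            s=5, a=5, method_id="mean", replicate_index=1, seed=0,
            rmse=rmse_value,
            mean_signed_rank_change=rank_change,
            mean_abs_rank_change=abs(rank_change),
        )

    def test_singleton(self):
        row = summarize_combination([self.record(0.2, -1.0)])
        assert row["rmse_min"] == row["rmse_max"] == 0.2
        assert row["rank_change_min"] == row["rank_change_max"] == -1.0

    def test_two_records_range(self):
        row = summarize_combination([self.record(0.1), self.record(0.3)])
        assert (row["rmse_min"], row["rmse_max"]) == (0.1, 0.3)

    def test_ranges_match_brute_force_scan(self):
        rng = np.random.default_rng(20)
        records = [self.record(r, c) for r, c in zip(rng.random(20), rng.normal(size=20))]
        row = summarize_combination(records)
        assert row["rmse_min"] == min(r.rmse for r in records)
        assert row["rmse_max"] == max(r.rmse for r in records)
        assert row["rank_change_min"] == min(r.mean_signed_rank_change for r in records)
        assert row["rank_change_max"] == max(r.mean_signed_rank_change for r in records)


def test_significance_policy_alpha():
    assert POLICY.per_test_alpha == pytest.approx(0.001 / 252)
    with pytest.raises(ValueError):
        SignificancePolicy(family_alpha=0.0)
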