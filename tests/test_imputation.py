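import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import random_masked_matrix
from toxpisim.data_io import ChemAssayMatrix
from toxpisim.imputation import (
    METHODS,
    ImputationConfig,
    impute,
    impute_binomial,
    impute_knn,
    impute_lls,
    impute_max,
    impute_mean,
    impute_min,
    impute_svd,
    impute_zero,
    resolve_knn_k,
)
from toxpisim.synthetic_data import SyntheticConfig, generate


def matrix(values) -> ChemAssayMatrix:
    values = np.asarray(values, dtype=float)
    return ChemAssayMatrix(
        [f"c{i}" for i in range(values.shape[0])],
        [f"a{j}" for j in range(values.shape[1])],
        values,
    )


class TestSimpleFills:
    def test_zero_fills_missing_positions_only(self, small_matrix):
        out = impute_zero(small_matrix)
        miss = small_matrix.missing_mask
        assert (out.values[miss] == 0).all()
        assert np.array_equal(out.values[~miss], small_matrix.values[~miss])

    def test_zero_on_all_missing(self):
        out = impute_zero(matrix([[np.nan, np.nan], [np.nan, np.nan]]))
        assert not out.values.any()

    def test_mean_forced_arithmetic(self):
        out = impute_mean(matrix([[0.0], [2.0], [np.nan], [4.0]]))
        assert out.values[2, 0] == 2.0

    def test_min_max_forced_extremes(self):
        m = matrix([[0.0], [2.0], [np.nan]])
        assert impute_min(m).values[2, 0] == 0.0
        assert impute_max(m).values[2, 0] == 2.0

    @pytest.mark.parametrize("fn", [impute_mean, impute_min, impute_max])
    def test_complete_matrix_unchanged(self, fn, synthetic_pair):
        truth = synthetic_pair.truth
        assert fn(truth).equals(truth)

    @pytest.mark.parametrize("fn", [impute_mean, impute_min, impute_max, impute_binomial])
    def test_all_missing_column_rejected(self, fn):
        m = matrix([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="100% missing"):
            fn(m)

    def test_min_equals_zero_when_observed_minima_are_zero(self):
        """The zero default and minimum-value fill coincide whenever every
        assay's observed minimum is 0 — the baseline-equivalence identity."""
        rng = np.random.default_rng(0)
        m = random_masked_matrix(rng, zero_fraction=0.5)
        assert (np.nanmin(m.values, axis=0) == 0).all()
        assert np.array_equal(impute_min(m).values, impute_zero(m).values)


class TestKnn:
    def test_identical_profiles_share_value(self):
        base = [1.0, 2.0, 3.0, 4.0]
        values = np.array([base, base, [np.nan] + base[1:]])
        out = impute_knn(matrix(values), ImputationConfig(knn_k=2))
        assert out.values[2, 0] == pytest.approx(1.0)

    def test_insufficient_neighbours_fall_back_to_zero(self):
        # chemical 2 overlaps nobody on >= 3 assays: correlation undefined
        values = np.array(
            [
                [1.0, 2.0, 3.0, 4.0, np.nan],
                [2.0, 4.0, 6.0, 8.0, 5.0],
                [np.nan, np.nan, np.nan, 1.0, 2.0],
            ]
        )
        out = impute_knn(matrix(values), ImputationConfig(knn_k=2))
        assert out.values[2, 0] == 0.0

    def test_auto_k_is_ceiling_sqrt_assays(self):
        assert resolve_knn_k(None, 1092) == 34
        assert resolve_knn_k(None, 25) == 5
        assert resolve_knn_k(ImputationConfig(knn_k=10), 1092) == 10

    def test_matches_exhaustive_oracle_seeded(self):
        rng = np.random.default_rng(42)
        m = random_masked_matrix(rng, n_chem=20, n_assay=15, missing_fraction=0.2)
        out = impute_knn(m, ImputationConfig(knn_k=4))
        expected = oracles.knn_fill(m.values, k=4)
        np.testing.assert_allclose(out.values, expected, atol=1e-10)


class TestBinomial:
    def test_degenerate_rates(self):
        all_zero = matrix([[0.0], [0.0], [np.nan]])
        assert impute_binomial(all_zero, rng=np.random.default_rng(0)).values[2, 0] == 0.0
        all_active = matrix([[1.5], [0.2], [np.nan]])
        assert impute_binomial(all_active, rng=np.random.default_rng(0)).values[2, 0] == 1.0

    def test_imputed_values_dichotomous_and_frequency_correct(self):
        values = np.full((1003, 1), np.nan)
        values[:3, 0] = [0.0, 0.0, 3.0]  # observed response rate 1/3
        m = matrix(values)
        fractions = [
            impute_binomial(m, rng=np.random.default_rng(seed)).values[3:, 0].mean()
            for seed in range(5)
        ]
        out = impute_binomial(m, rng=np.random.default_rng(0))
        assert set(np.unique(out.values[3:, 0])) <= {0.0, 1.0}
        assert abs(np.mean(fractions) - 1 / 3) < 0.05

    def test_fixed_seed_is_deterministic(self, synthetic_pair):
        a = impute_binomial(synthetic_pair.observed, ImputationConfig(seed=5))
        b = impute_binomial(synthetic_pair.observed, ImputationConfig(seed=5))
        assert a.equals(b)


class TestLls:
    def test_recovers_exact_affine_relation(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 2, size=12)
        b = rng.uniform(0, 2, size=12)
        target = 2 * a + 1
        values = np.column_stack([a, b, target])
        values[[2, 7], 2] = np.nan
        out = impute_lls(matrix(values), ImputationConfig(lls_k=2))
        np.testing.assert_allclose(out.values[[2, 7], 2], 2 * a[[2, 7]] + 1, atol=1e-6)

    def test_complete_matrix_unchanged(self, synthetic_pair):
        truth = synthetic_pair.truth
        assert impute_lls(truth, ImputationConfig(lls_k=2)).equals(truth)

    def test_too_few_assays_rejected(self):
        with pytest.raises(ValueError, match="lls_k"):
            impute_lls(matrix([[1.0, np.nan], [2.0, 1.0]]), ImputationConfig(lls_k=2))

    def test_matches_normal_equations_oracle_seeded(self):
        rng = np.random.default_rng(7)
        m = random_masked_matrix(rng, n_chem=15, n_assay=10, missing_fraction=0.15)
        out = impute_lls(m, ImputationConfig(lls_k=2))
        expected = oracles.lls_fill(m.values, k=2)
        np.testing.assert_allclose(out.values, expected, atol=1e-6)


class TestSvd:
    def test_rank_one_completion_is_exact(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(0.5, 2, size=12)
        v = rng.uniform(0.5, 2, size=9)
        truth = np.outer(u, v)
        values = truth.copy()
        mask = rng.random(values.shape) < 0.1
        mask[0, 0] = False  # keep corners anchored
        values[mask] = np.nan
        out = impute_svd(
            matrix(values), ImputationConfig(svd_rank=1, svd_tolerance=1e-10)
        )
        np.testing.assert_allclose(out.values[mask], truth[mask], atol=1e-3)

    def test_complete_matrix_unchanged(self, synthetic_pair):
        truth = synthetic_pair.truth
        assert impute_svd(truth).equals(truth)

    def test_beats_zero_fill_on_low_rank_ground_truth(self):
        cfg = SyntheticConfig(
            n_chemicals=30,
            n_sources=2,
            assays_per_source_range=(10, 10),
            latent_rank=2,
            inactive_fraction=0.0,
            noise_sd=0.05,
            chem_missing_range=(0.2, 0.2),
            assay_missing_range=(1.0, 1.0),
            seed=23,
        )
        observed, truth, _ = generate(cfg)
        miss = observed.missing_mask
        svd_vals = impute_svd(observed, ImputationConfig(svd_rank=2)).values
        zero_vals = impute_zero(observed).values
        err = lambda v: np.sqrt(np.mean((v[miss] - truth.values[miss]) ** 2))
        assert err(svd_vals) < err(zero_vals)


class TestInvariants:
    @pytest.mark.parametrize("method", sorted(METHODS))
    def test_complete_output_and_observed_cells_untouched(self, method, synthetic_pair):
        m = synthetic_pair.observed
        out = impute(m, method, ImputationConfig(), np.random.default_rng(1))
        assert out.is_complete()
        obs = ~m.missing_mask
        assert np.array_equal(out.values[obs], m.values[obs])

    def test_unknown_method_rejected(self, synthetic_pair):
        with pytest.raises(ValueError, match="unknown imputation method"):
            impute(synthetic_pair.observed, "oracle")

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_min_mean_max_ordering(self, seed):
        rng = np.random.default_rng(seed)
        m = random_masked_matrix(rng)
        miss = m.missing_mask
        lo = impute_min(m).values[miss]
        mid = impute_mean(m).values[miss]
        hi = impute_max(m).values[miss]
        assert (lo <= mid + 1e-12).all() and (mid <= hi + 1e-12).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_knn_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        m = random_masked_matrix(rng, n_chem=10, n_assay=8)
        out = impute_knn(m, ImputationConfig(knn_k=3))
        np.testing.assert_allclose(out.values, oracles.knn_fill(m.values, 3), atol=1e-10)
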