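import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import biftwin as bt
from biftwin.twin_sem import (
    ModelSpec,
    aggregate_standardized_effects,
    expected_cov_cp,
    expected_cov_ip,
    fiml_minus2ll,
    fit_model,
    shares_within_source,
    standardized_effects,
)

from helpers import (
    bifactor_loadings,
    make_cp,
    make_ip,
    path_tracing_cov,
    random_cp,
    random_ip,
    small_structure,
)


class TestModelSpec:
    def test_e_required(self, small4):
        with pytest.raises(ValueError, match="E must always be present"):
            ModelSpec("CP", frozenset("AC"), small4)

    def test_bad_family(self, small4):
        with pytest.raises(ValueError, match="family"):
            ModelSpec("XY", frozenset("ACE"), small4)

    def test_nesting(self, small4):
        ace = ModelSpec("CP", frozenset("ACE"), small4)
        ae = ModelSpec("CP", frozenset("AE"), small4)
        assert ae.is_nested_in(ace)
        assert not ace.is_nested_in(ae)


class TestExpectedCovCP:
    def test_e_only_cross_twin_zero(self, small4):
        params = make_cp(small4, factor_ace=(0, 0, 1), unique_ace=(0, 0, 0.4))
        for z in ("MZ", "DZ"):
            sigma = expected_cov_cp(params, z)
            assert np.allclose(sigma[:4, 4:], 0.0)

    def test_pure_additive_path_tracing_values(self, small4):
        # item 1 loads the general factor with 1, factor is all-A
        lam = np.zeros((4, 3))
        lam[0, 0] = 1.0
        fp = np.tile([1.0, 0.0, 0.0], (3, 1))
        up = np.zeros((4, 3))
        params = bt.CPParameterSet(bt.LoadingMatrix(lam, small4), fp, up)
        assert expected_cov_cp(params, "MZ")[0, 4] == pytest.approx(1.0)
        assert expected_cov_cp(params, "DZ")[0, 4] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_path_tracing_oracle(self, small4, seed):
        params = random_cp(small4, np.random.default_rng(seed))
        for z in ("MZ", "DZ"):
            oracle = path_tracing_cov(params, z)
            np.testing.assert_allclose(expected_cov_cp(params, z), oracle,
                                       atol=1e-10)

    def test_invalid_params_rejected(self, small4):
        params = make_cp(small4)
        params.factor_paths = params.factor_paths * 2
        with pytest.raises(ValueError):
            expected_cov_cp(params, "MZ")


class TestExpectedCovIP:
    def test_no_a_no_c_means_no_zygosity_difference(self, small4):
        params = make_ip(small4, loads={"E": (0.5, 0.3)}, unique_ace=(0, 0, 0.5))
        np.testing.assert_allclose(expected_cov_ip(params, "MZ"),
                                   expected_cov_ip(params, "DZ"))

    def test_single_additive_loading_path_tracing(self, small4):
        params = make_ip(small4, loads={}, unique_ace=(0, 0, 0.5))
        lamA = np.zeros((4, 3))
        lamA[0, 0] = 0.3
        params.lambda_A = bt.LoadingMatrix(lamA, small4)
        assert expected_cov_ip(params, "MZ")[0, 4] == pytest.approx(0.09)
        assert expected_cov_ip(params, "DZ")[0, 4] == pytest.approx(0.045)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_path_tracing_oracle(self, small4, seed):
        params = random_ip(small4, np.random.default_rng(seed))
        for z in ("MZ", "DZ"):
            oracle = path_tracing_cov(params, z)
            np.testing.assert_allclose(expected_cov_ip(params, z), oracle,
                                       atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_mz_cross_block_dominates_dz(self, small4, seed):
        rng = np.random.default_rng(seed)
        for params in (random_cp(small4, rng), random_ip(small4, rng)):
            cov = bt.expected_covariances(params)
            diff = (cov.sigma_MZ - cov.sigma_DZ)[:4, 4:]
            assert np.all(np.linalg.eigvalsh((diff + diff.T) / 2) > -1e-10)
            assert np.all(diff >= -1e-12)


class TestFIML:
    def test_complete_data_equals_direct_mvn(self, small_dataset, cp_params_small):
        cov = bt.expected_covariances(cp_params_small)
        val = fiml_minus2ll(small_dataset, cov.sigma_MZ, cov.sigma_DZ)
        direct = 0.0
        for z, sig in (("MZ", cov.sigma_MZ), ("DZ", cov.sigma_DZ)):
            V = small_dataset.items[small_dataset.zygosity_mask(z)].reshape(-1, 8)
            direct += -2.0 * multivariate_normal(mean=np.zeros(8),
                                                 cov=sig).logpdf(V).sum()
        assert val == pytest.approx(direct, abs=1e-6)

    def test_single_observed_cell_scalar_density(self, small4):
        items = np.full((1, 2, 4), np.nan)
        items[0, 0, 0] = 0.0
        data = bt.TwinPairDataset(pair_ids=np.array(["p"], dtype=object),
                                  zygosity=np.array(["MZ"], dtype=object),
                                  items=items, covariates=np.zeros((1, 2, 3)))
        val = fiml_minus2ll(data, np.eye(8), np.eye(8))
        assert val == pytest.approx(np.log(2 * np.pi), abs=1e-12)

    def test_fully_missing_pair_contributes_zero(self, small4):
        items = np.full((2, 2, 4), np.nan)
        items[0] = 0.5
        data = bt.TwinPairDataset(pair_ids=np.array(["p", "q"], dtype=object),
                                  zygosity=np.array(["MZ", "MZ"], dtype=object),
                                  items=items, covariates=np.zeros((2, 2, 3)))
        both = fiml_minus2ll(data, np.eye(8), np.eye(8))
        only = fiml_minus2ll(data.subset([0]), np.eye(8), np.eye(8))
        assert both == pytest.approx(only, abs=1e-12)

    def test_masking_independent_variable_marginalizes(self, small4):
        rng = np.random.default_rng(0)
        sigma = np.eye(8)  # all variables independent under the model
        items = rng.standard_normal((5, 2, 4))
        data = bt.TwinPairDataset(
            pair_ids=np.array([f"p{i}" for i in range(5)], dtype=object),
            zygosity=np.array(["MZ", "MZ", "DZ", "DZ", "DZ"], dtype=object),
            items=items, covariates=np.zeros((5, 2, 3)))
        full = fiml_minus2ll(data, sigma, sigma)
        masked = bt.TwinPairDataset(
            pair_ids=data.pair_ids, zygosity=data.zygosity,
            items=data.items.copy(), covariates=data.covariates)
        x = masked.items[2, 1, 3]
        masked.items[2, 1, 3] = np.nan
        removed = np.log(2 * np.pi) + x**2
        assert fiml_minus2ll(masked, sigma, sigma) == pytest.approx(
            full - removed, abs=1e-9)

    def test_singular_submatrix_reported_with_pair(self, small_dataset):
        sigma = np.zeros((8, 8))
        with pytest.raises(np.linalg.LinAlgError, match="pairs"):
            fiml_minus2ll(small_dataset, sigma, sigma)

    def test_means_shift(self, small_dataset, cp_params_small):
        cov = bt.expected_covariances(cp_params_small)
        mu = np.full(8, 0.3)
        shifted = fiml_minus2ll(small_dataset, cov.sigma_MZ, cov.sigma_DZ, means=mu)
        base = fiml_minus2ll(small_dataset, cov.sigma_MZ, cov.sigma_DZ)
        assert shifted != pytest.approx(base)


class TestFitModel:
    def test_e_only_recovery(self, small4):
        params = make_cp(small4, general=0.0, group=0.0,
                         factor_ace=(0, 0, 1), unique_ace=(0, 0, 0.64))
        data = bt.simulate_twins(bt.SimulationConfig(
            n_MZ=2000, n_DZ=2000, params=params, seed=12))
        spec = ModelSpec("CP", frozenset("E"), small4, unique_ace=False)
        fit = fit_model(data, spec, n_starts=2, seed=0)
        assert fit.converged
        e2 = fit.params.unique_paths[:, 2] ** 2
        # total item variance 0.64 must land in unique e (loadings soak the rest)
        v = (fit.params.lambda_p.values**2).sum(axis=1) + e2
        assert np.allclose(v, 0.64, atol=0.03)

    def test_jittered_starts_agree(self, small_dataset, small4):
        spec = ModelSpec("CP", frozenset("AE"), small4, unique_ace=False)
        vals = [fit_model(small_dataset, spec, n_starts=1, jitter=0.1,
                          seed=s).minus2LL for s in range(5)]
        assert max(vals) - min(vals) < 0.01

    def test_likelihood_invariant_to_column_sign_flip(self, small_dataset,
                                                      cp_params_small):
        cov = bt.expected_covariances(cp_params_small)
        base = fiml_minus2ll(small_dataset, cov.sigma_MZ, cov.sigma_DZ)
        structure = cp_params_small.structure
        lam = cp_params_small.lambda_p.values.copy()
        lam[:, 1] *= -1.0
        flipped = bt.CPParameterSet(bt.LoadingMatrix(lam, structure),
                                    cp_params_small.factor_paths,
                                    cp_params_small.unique_paths)
        cov2 = bt.expected_covariances(flipped)
        assert fiml_minus2ll(small_dataset, cov2.sigma_MZ,
                             cov2.sigma_DZ) == pytest.approx(base, abs=1e-9)

    def test_cp_constraint_holds_after_fit(self, small_dataset, small4):
        spec = ModelSpec("CP", frozenset("ACE"), small4)
        fit = fit_model(small_dataset, spec, n_starts=1, seed=0)
        ss = (fit.params.factor_paths**2).sum(axis=1)
        np.testing.assert_allclose(ss, 1.0, atol=1e-6)

    def test_fit_with_missing_data_runs(self, small_dataset_missing, small4):
        spec = ModelSpec("CP", frozenset("AE"), small4, unique_ace=False)
        fit = fit_model(small_dataset_missing, spec, n_starts=1, seed=0)
        assert np.isfinite(fit.minus2LL)
        assert fit.n_pairs_used == 300

    def test_ip_fit_small(self, small4, ip_params_small):
        data = bt.simulate_twins(bt.SimulationConfig(
            n_MZ=800, n_DZ=800, params=ip_params_small, seed=21))
        spec = ModelSpec("IP", frozenset("ACE"), small4)
        fit = fit_model(data, spec, n_starts=2, seed=0)
        assert fit.converged
        # within-twin implied covariance close to the generator's
        W_true = expected_cov_ip(ip_params_small, "MZ")[:4, :4]
        W_est = expected_cov_ip(fit.params, "MZ")[:4, :4]
        assert np.max(np.abs(W_true - W_est)) < 0.08

    def test_bad_start_length_rejected(self, small_dataset, small4):
        spec = ModelSpec("CP", frozenset("AE"), small4)
        with pytest.raises(ValueError, match="length"):
            fit_model(small_dataset, spec, start=np.zeros(3))


class TestStandardizedEffects:
    @pytest.mark.parametrize("seed", range(3))
    def test_rows_sum_to_one_cp_and_ip(self, small4, seed):
        rng = np.random.default_rng(seed)
        for params in (random_cp(small4, rng), random_ip(small4, rng)):
            table = standardized_effects(params)
            np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-10)

    def test_cp_factor_share_matches_heritability(self, small4):
        params = make_cp(small4, factor_ace=(0.4, 0.0, 0.6))
        table = standardized_effects(params)
        lam2 = params.lambda_p.values[0, 0] ** 2
        v = (params.lambda_p.values[0] ** 2).sum() + (params.unique_paths[0] ** 2).sum()
        assert table.iloc[0][("A", "general")] == pytest.approx(0.4 * lam2 / v)


class TestAggregation:
    def test_published_a_column_shares(self):
        shares = shares_within_source([0.08, 0.03, 0.03, 0.02])
        np.testing.assert_allclose(shares, [0.5, 0.1875, 0.1875, 0.125])

    def test_concentrated_general(self, small4):
        levels = ["general", "g1", "g2", "unique"]
        cols = pd.MultiIndex.from_product([("A", "C", "E"), levels],
                                          names=["source", "level"])
        vals = np.zeros((4, 12))
        vals[:, 0] = 0.3   # A-general only
        vals[:, 8:] = 1.0  # E filler
        table = pd.DataFrame(vals, columns=cols)
        agg = aggregate_standardized_effects(table)
        assert agg["A"]["shares"]["general"] == pytest.approx(1.0)
        assert agg["A"]["shares"]["unique"] == 0.0

    def test_uniform_levels(self):
        assert np.allclose(shares_within_source([0.1] * 4), 0.25)

    def test_missing_table_rejected(self, small4):
        fit = bt.FitResult(spec=None, params=None, minus2LL=0.0,
                           n_free_params=0, n_pairs_used=0, converged=True)
        with pytest.raises(ValueError, match="standardized"):
            aggregate_standardized_effects(fit)
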