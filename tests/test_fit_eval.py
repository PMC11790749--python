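import math
import warnings

import numpy as np
import pytest

import biftwin as bt
from biftwin.fit_eval import (
    FitStatistics,
    bootstrap_ci,
    fit_statistics,
    lrt,
    twin_bifactor_indices,
)
from biftwin.psychometrics import ecv
from biftwin.twin_sem import (
    FitResult,
    ModelSpec,
    fit_independence,
    fit_model,
    fit_saturated,
)

from helpers import make_cp, make_ip


def _bare_fit(minus2LL, k, spec=None, n=500):
    return FitResult(spec=spec, params=None, minus2LL=minus2LL,
                     n_free_params=k, n_pairs_used=n, converged=True)


class TestFitStatistics:
    def test_saturated_self_comparison(self):
        sat = _bare_fit(1000.0, 72)
        indep = _bare_fit(1500.0, 16)
        model = _bare_fit(1000.0, 20)
        st = fit_statistics(model, sat, indep, N=500)
        assert st.chi2_vs_saturated == 0.0
        assert st.rmsea == 0.0
        assert st.cfi == 1.0

    def test_aic_bic_identities(self):
        sat = _bare_fit(900.0, 72)
        indep = _bare_fit(1500.0, 16)
        model = _bare_fit(1000.0, 10)
        st = fit_statistics(model, sat, indep, N=500)
        assert st.aic == pytest.approx(1020.0, abs=1e-12)
        assert st.bic == pytest.approx(1000.0 + 10 * math.log(500), abs=1e-12)

    def test_formula_oracle(self):
        # independently recoded formulas
        m2_model, k_model = 1234.5, 30
        m2_sat, k_sat = 1100.0, 80
        m2_ind, k_ind = 1700.0, 16
        N = 400
        st = fit_statistics(_bare_fit(m2_model, k_model),
                            _bare_fit(m2_sat, k_sat),
                            _bare_fit(m2_ind, k_ind), N=N)
        chi2 = m2_model - m2_sat
        df = k_sat - k_model
        assert st.rmsea == pytest.approx(
            math.sqrt(max(0.0, chi2 - df) / (df * (N - 1))))
        chi2_b, df_b = m2_ind - m2_sat, k_sat - k_ind
        assert st.cfi == pytest.approx(
            1 - max(0.0, chi2 - df) / max(chi2_b - df_b, chi2 - df, 0.0))

    def test_location_invariance(self):
        indep = _bare_fit(1500.0, 16)
        a = fit_statistics(_bare_fit(1000.0, 20), _bare_fit(900.0, 72),
                           indep, N=500)
        shift = 250.0
        b = fit_statistics(_bare_fit(1000.0 + shift, 20),
                           _bare_fit(900.0 + shift, 72),
                           _bare_fit(1500.0 + shift, 16), N=500)
        assert b.rmsea == pytest.approx(a.rmsea, abs=1e-12)
        assert b.cfi == pytest.approx(a.cfi, abs=1e-12)

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError, match="parameters"):
            fit_statistics(_bare_fit(1000.0, 80), _bare_fit(900.0, 72),
                           _bare_fit(1500.0, 16), N=500)

    def test_identity_violation_rejected(self):
        with pytest.raises(ValueError, match="AIC identity"):
            FitStatistics(minus2LL=100.0, aic=105.0, bic=120.0, rmsea=0.0,
                          cfi=1.0, df=3, chi2_vs_saturated=0.0,
                          n_free_params=10, n=100)


class TestLRT:
    def test_identical_fits(self):
        full = _bare_fit(1000.0, 20)
        nested = _bare_fit(1000.0, 20)
        res = lrt(full, nested)
        assert res.delta_chi2 == 0.0
        assert res.p_value == 1.0

    def test_chi2_quantile_oracle(self):
        res = lrt(_bare_fit(1000.0, 20), _bare_fit(1003.84, 19))
        # df=1 tail via the error function, independent of scipy.stats.chi2
        p_oracle = math.erfc(math.sqrt(3.84 / 2.0))
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(0.050, abs=5e-4)

    def test_negative_delta_clipped(self):
        res = lrt(_bare_fit(1000.0, 20), _bare_fit(999.99, 18))
        assert res.delta_chi2 == 0.0

    def test_non_nested_specs_rejected(self, small4):
        ace = ModelSpec("CP", frozenset("ACE"), small4)
        ce = ModelSpec("CP", frozenset("CE"), small4)
        ae = ModelSpec("CP", frozenset("AE"), small4)
        with pytest.raises(ValueError, match="not nested"):
            lrt(_bare_fit(1000.0, 20, spec=ae), _bare_fit(1001.0, 18, spec=ce))


class TestBootstrap:
    @pytest.fixture(scope="class")
    def boot_setup(self, small4):
        params = make_cp(small4, factor_ace=(0.5, 0.0, 0.5),
                         unique_ace=(0.0, 0.0, 0.35))
        data = bt.simulate_twins(bt.SimulationConfig(
            n_MZ=250, n_DZ=250, params=params, seed=31))
        spec = ModelSpec("CP", frozenset("AE"), small4, unique_ace=False)
        return data, spec

    def test_requires_two_replicates(self, boot_setup):
        data, spec = boot_setup
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_ci(data, spec, B=1, seed=0, statistic=lambda f: {"x": 1.0})

    def test_degenerate_statistic_interval(self, boot_setup):
        data, spec = boot_setup
        res = bootstrap_ci(data, spec, B=9, seed=0,
                           statistic=lambda f: {"const": 2.5})
        assert res["intervals"]["const"] == (2.5, 2.5)

    def test_fixed_seed_reproducible(self, boot_setup):
        data, spec = boot_setup
        stat = lambda f: {"a2": float(f.params.factor_paths[0, 0] ** 2)}
        r1 = bootstrap_ci(data, spec, B=19, seed=3, statistic=stat)
        r2 = bootstrap_ci(data, spec, B=19, seed=3, statistic=stat)
        assert r1["intervals"] == r2["intervals"]

    def test_interval_covers_generator(self, boot_setup):
        data, spec = boot_setup
        stat = lambda f: {"a2": float(f.params.factor_paths[0, 0] ** 2)}
        res = bootstrap_ci(data, spec, B=199, seed=1, statistic=stat)
        lo, hi = res["intervals"]["a2"]
        assert lo <= 0.5 <= hi
        assert res["n_failed"] <= 0.05 * 199


class TestTwinBifactorIndices:
    def test_cp_fit_rejected(self, small4):
        params = make_cp(small4)
        fit = FitResult(spec=None, params=params, minus2LL=0.0,
                        n_free_params=0, n_pairs_used=0, converged=True)
        with pytest.raises(ValueError, match="IP-family"):
            twin_bifactor_indices(fit)

    def test_zero_general_source_fails_cutoffs(self, small4):
        params = make_ip(small4, loads={"A": (0.0, 0.4), "C": (0.3, 0.2),
                                        "E": (0.4, 0.3)})
        fit = FitResult(spec=None, params=params, minus2LL=0.0,
                        n_free_params=0, n_pairs_used=0, converged=True)
        reports = twin_bifactor_indices(fit)
        assert reports["A"].ecv == pytest.approx(0.0)
        assert not reports["A"].omega_h_pass and not reports["A"].h_pass

    def test_strong_e_weak_c_qualitative_pattern(self, small4):
        params = make_ip(small4, loads={"A": (0.25, 0.15), "C": (0.03, 0.12),
                                        "E": (0.60, 0.25)},
                         unique_ace=(0.02, 0.0, 0.30))
        fit = FitResult(spec=None, params=params, minus2LL=0.0,
                        n_free_params=0, n_pairs_used=0, converged=True)
        reports = twin_bifactor_indices(fit)
        assert reports["E"].omega_h_pass and reports["E"].h_pass
        assert not reports["C"].omega_h_pass and not reports["C"].h_pass

    def test_ecv_delegates_to_source_matrix(self, small4):
        params = make_ip(small4)
        fit = FitResult(spec=None, params=params, minus2LL=0.0,
                        n_free_params=0, n_pairs_used=0, converged=True)
        reports = twin_bifactor_indices(fit)
        lam = {c: params.source(c).values for c in ("A", "C", "E")}
        v = sum((m**2).sum(axis=1) for m in lam.values()) \
            + (params.unique_paths**2).sum(axis=1)
        std_A = lam["A"] / np.sqrt(v)[:, None]
        assert reports["A"].ecv == pytest.approx(ecv(std_A), abs=1e-12)


class TestReferenceModels:
    def test_saturated_beats_structured(self, small_dataset, small4):
        sat = fit_saturated(small_dataset)
        spec = ModelSpec("CP", frozenset("AE"), small4, unique_ace=False)
        fit = fit_model(small_dataset, spec, n_starts=1, seed=0)
        assert sat.minus2LL <= fit.minus2LL + 1e-6

    def test_independence_worst(self, small_dataset, small4):
        indep = fit_independence(small_dataset)
        spec = ModelSpec("CP", frozenset("AE"), small4, unique_ace=False)
        fit = fit_model(small_dataset, spec, n_starts=1, seed=0)
        assert indep.minus2LL >= fit.minus2LL

    def test_saturated_em_matches_closed_form_under_mcar(self, small_dataset_missing):
        # EM route must at least reach the complete-data likelihood ordering
        sat = fit_saturated(small_dataset_missing)
        indep = fit_independence(small_dataset_missing)
        assert sat.minus2LL < indep.minus2LL
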