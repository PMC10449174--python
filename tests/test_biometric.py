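"""Implied moments, FIML likelihood and its gradient, twin correlations."""

import math

import numpy as np
import pytest
from scipy import stats
from statsmodels.tools.numdiff import approx_fprime

from acebeta.biometric import (
    ContractError,
    ModelSpec,
    ParameterSet,
    fiml_neg2ll,
    implied_moments,
    parameter_universe,
    select_family,
    spec_by_name,
    twin_correlations,
)
from acebeta.preprocess import PreparedData
from acebeta.synthetic import GeneratorConfig, simulate_pairs

from conftest import full_trivariate_spec, theta_for

UNI_GRADES = ModelSpec("uni", ("grades",), ("a22", "c22", "e22", "mu2"))


class TestImpliedMoments:
    def test_pure_additive_genetic_limit(self):
        th = theta_for(UNI_GRADES, {"a22": 1.0, "e22": 0.0})
        mz = implied_moments(UNI_GRADES, th, "MZ")
        dz = implied_moments(UNI_GRADES, th, "DZ")
        assert mz.cov[0, 0] == pytest.approx(1.0)
        assert mz.cov[0, 1] == pytest.approx(1.0)
        assert dz.cov[0, 1] == pytest.approx(0.5)

    def test_hand_path_tracing_arithmetic(self):
        # var = a^2+c^2+e^2, MZ cov = a^2+c^2, DZ cov = a^2/2+c^2
        th = theta_for(UNI_GRADES, {"a22": 0.56, "c22": 0.37, "e22": 0.37})
        mz = implied_moments(UNI_GRADES, th, "MZ")
        dz = implied_moments(UNI_GRADES, th, "DZ")
        assert mz.cov[0, 0] == pytest.approx(0.5874, abs=1e-4)
        assert mz.cov[0, 1] == pytest.approx(0.4505, abs=1e-4)
        assert dz.cov[0, 1] == pytest.approx(0.2937, abs=1e-4)

    def test_block_structure_invariants(self, rng):
        spec = full_trivariate_spec()
        th = ParameterSet(spec, rng.normal(0.2, 0.2, spec.n_free))
        mm = implied_moments(spec, th, "DZ", m=0.7)
        assert np.allclose(mm.cov, mm.cov.T)
        assert np.allclose(mm.cov[:3, :3], mm.cov[3:, 3:])  # within-twin blocks equal
        assert np.allclose(mm.cov[:3, 3:], mm.cov[3:, :3].T)
        assert np.allclose(mm.mean[:3], mm.mean[3:])

    def test_simulation_moment_oracle(self):
        # empirical covariance of a large simulated cohort matches the
        # implied moments within Monte-Carlo error
        cfg = GeneratorConfig(n_pairs=120_000, missing_rates={}, m_fixed=-1.0,
                              seed=2, prop_mz=0.0)
        d = simulate_pairs(cfg)
        spec = full_trivariate_spec()
        th = theta_for(spec, cfg.theta)
        mm = implied_moments(spec, th, "DZ", m=-1.0)
        emp = np.cov(d.y, rowvar=False)
        nn = cfg.n_pairs
        se = np.sqrt((np.outer(np.diag(mm.cov), np.diag(mm.cov)) + mm.cov**2) / nn)
        assert np.all(np.abs(emp - mm.cov) < 4.0 * se)
        mean_se = np.sqrt(np.diag(mm.cov) / nn)
        assert np.all(np.abs(d.y.mean(0) - mm.mean) < 4.0 * mean_se)

    def test_unmoderated_cov_constant_in_m(self):
        spec = spec_by_name("M2d")
        th = theta_for(spec, {"a11": 0.6, "c11": 0.4, "e11": 0.6, "a22": 0.5,
                              "c22": 0.3, "e22": 0.4, "a33": 0.7, "e33": 0.5,
                              "beta32": 0.2, "b1": 0.3, "b2": 0.2, "b3": 0.3})
        m0 = implied_moments(spec, th, "MZ", m=0.0)
        m2 = implied_moments(spec, th, "MZ", m=2.0)
        assert np.allclose(m0.cov, m2.cov)
        # means shift by the reduced-form b effects
        assert not np.allclose(m0.mean, m2.mean)

    def test_dz_rho_one_equalizes_zygosities(self, rng):
        spec = full_trivariate_spec(dz_genetic_correlation=1.0)
        th = ParameterSet(spec, rng.normal(0.2, 0.2, spec.n_free))
        mz = implied_moments(spec, th, "MZ", m=0.3)
        dz = implied_moments(spec, th, "DZ", m=0.3)
        assert np.allclose(mz.cov, dz.cov)

    def test_ade_latent_correlations(self):
        # univariate ADE: cross-twin weights (1, 1) MZ and (0.5, 0.25) DZ
        spec = ModelSpec("ade", ("grades",), ("a22", "c22", "e22", "mu2"), family="ADE")
        th = theta_for(spec, {"a22": 0.6, "c22": 0.5, "e22": 0.4})
        mz = implied_moments(spec, th, "MZ")
        dz = implied_moments(spec, th, "DZ")
        assert mz.cov[0, 1] == pytest.approx(0.36 + 0.25)
        assert dz.cov[0, 1] == pytest.approx(0.5 * 0.36 + 0.25 * 0.25)


class TestFiml:
    def test_standard_normal_closed_form(self):
        spec = ModelSpec("iso", ("iq", "grades", "exp"),
                         ("e11", "e22", "e33", "mu1", "mu2", "mu3"))
        th = theta_for(spec, {"e11": 1.0, "e22": 1.0, "e33": 1.0})
        data = PreparedData(zygosity=np.array(["MZ"]), m=np.zeros(1), y=np.zeros((1, 6)))
        val = fiml_neg2ll(spec, th, data)
        assert val == pytest.approx(6.0 * math.log(2.0 * math.pi), abs=1e-10)

    def test_complete_data_matches_gaussian_oracle(self, complete_cohort, rng):
        spec = full_trivariate_spec()
        th = ParameterSet(spec, rng.normal(0.25, 0.15, spec.n_free))
        for e in ("e11", "e22", "e33"):
            th.values[spec.free_paths.index(e)] = 0.6
        val = fiml_neg2ll(spec, th, complete_cohort)
        oracle = 0.0
        for i in range(complete_cohort.n_pairs):
            mm = implied_moments(spec, th, complete_cohort.zygosity[i],
                                 complete_cohort.m[i])
            oracle += -2.0 * stats.multivariate_normal.logpdf(
                complete_cohort.y[i], mm.mean, mm.cov)
        assert val == pytest.approx(oracle, abs=1e-8)

    def test_marginalization_matches_submatrix_oracle(self, rng):
        spec = full_trivariate_spec()
        th = ParameterSet(spec, rng.normal(0.25, 0.15, spec.n_free))
        for e in ("e11", "e22", "e33"):
            th.values[spec.free_paths.index(e)] = 0.6
        y = rng.normal(size=(1, 6))
        y[0, 5] = np.nan  # expectation of twin 2 missing
        data = PreparedData(zygosity=np.array(["DZ"]), m=np.array([0.4]), y=y)
        val = fiml_neg2ll(spec, th, data)
        mm = implied_moments(spec, th, "DZ", 0.4)
        o = [0, 1, 2, 3, 4]
        oracle = -2.0 * stats.multivariate_normal.logpdf(
            y[0, o], mm.mean[o], mm.cov[np.ix_(o, o)])
        assert val == pytest.approx(oracle, abs=1e-8)

    def test_gradient_matches_numeric(self, rng):
        d = simulate_pairs(GeneratorConfig(n_pairs=150, seed=5))
        spec = spec_by_name("M3b")
        x = rng.normal(0.3, 0.1, spec.n_free)
        for e in ("e11", "e22", "e33"):
            x[spec.free_paths.index(e)] = 0.5
        _, g = fiml_neg2ll(spec, ParameterSet(spec, x), d, return_grad=True)
        gn = approx_fprime(
            x, lambda xx: fiml_neg2ll(spec, ParameterSet(spec, xx), d), centered=True)
        assert np.allclose(g, gn, atol=1e-4, rtol=1e-6)

    def test_empty_pair_is_contract_error(self):
        spec = UNI_GRADES
        th = theta_for(spec, {"a22": 0.5, "e22": 0.5})
        y = np.full((1, 6), np.nan)
        data = PreparedData(zygosity=np.array(["MZ"]), m=np.zeros(1), y=y)
        with pytest.raises(ContractError, match="dropped upstream"):
            fiml_neg2ll(spec, th, data)

    def test_non_positive_definite_penalized(self):
        th = theta_for(UNI_GRADES, {"a22": 0.0, "c22": 0.0, "e22": 0.0})
        y = np.full((1, 6), np.nan)
        y[0, [1, 4]] = 0.0
        data = PreparedData(zygosity=np.array(["MZ"]), m=np.zeros(1), y=y)
        assert fiml_neg2ll(UNI_GRADES, th, data) >= 1e10


class TestTwinCorrelations:
    def test_identical_mz_cotwins_give_r_one(self):
        y = np.full((20, 6), np.nan)
        vals = np.linspace(-1, 1, 20)
        y[:, 1] = vals
        y[:, 4] = vals
        data = PreparedData(zygosity=np.array(["MZ"] * 10 + ["DZ"] * 10),
                            m=np.zeros(20), y=y)
        corrs = twin_correlations(data)
        assert corrs["grades"]["rMZ"] == pytest.approx(1.0)

    def test_double_entry_invariant_to_twin_order(self, latent_cohort):
        corrs = twin_correlations(latent_cohort)
        swapped = PreparedData(
            zygosity=latent_cohort.zygosity,
            m=latent_cohort.m,
            y=latent_cohort.y[:, [3, 4, 5, 0, 1, 2]],
        )
        corrs2 = twin_correlations(swapped)
        for pheno in corrs:
            for k in corrs[pheno]:
                assert corrs[pheno][k] == pytest.approx(corrs2[pheno][k], abs=1e-12)

    def test_ace_simulation_recovers_expected_correlations(self):
        # rMZ ~ a^2+c^2, rDZ ~ a^2/2+c^2 (variance-standardized)
        a, c, e = 0.6, 0.4, 0.69
        theta = {"a22": a, "c22": c, "e22": e}
        cfg = GeneratorConfig(n_pairs=100_000, theta=theta, missing_rates={}, seed=8)
        d = simulate_pairs(cfg)
        tot = a * a + c * c + e * e
        expect_mz = (a * a + c * c) / tot
        expect_dz = (0.5 * a * a + c * c) / tot
        corrs = twin_correlations(d)["grades"]
        se = 1.0 / math.sqrt(cfg.n_pairs)  # conservative MC scale
        assert abs(corrs["rMZ"] - expect_mz) < 3 * se * 2
        assert abs(corrs["rDZ"] - expect_dz) < 3 * se * 2

    def test_insufficient_pairs_warn(self):
        y = np.full((3, 6), np.nan)
        y[:, 1] = [0.0, 1.0, 2.0]
        data = PreparedData(zygosity=np.array(["MZ", "MZ", "DZ"]), m=np.zeros(3), y=y)
        with pytest.warns(UserWarning):
            corrs = twin_correlations(data)
        assert corrs["grades"]["rMZ"] is None


class TestSelectFamily:
    @pytest.mark.parametrize(
        "rmz,rdz,expected",
        [(0.8, 0.5, "ACE"), (0.8, 0.3, "ADE"), (0.8, 0.4, "ACE")],  # boundary -> ACE
    )
    def test_rule(self, rmz, rdz, expected):
        out = select_family({"grades": {"rMZ": rmz, "rDZ": rdz}})
        assert out["grades"] == expected


class TestImpliedMomentProperties:
    """Structural invariants over random parameter values."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    def _theta(spec, draw):
        vals = np.array(draw, dtype=float)
        return ParameterSet(spec, vals)

    @given(st.lists(st.floats(-0.9, 0.9), min_size=33, max_size=33),
           st.floats(-2.0, 2.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_cov_is_symmetric_psd_with_exchangeable_twins(self, draw, m):
        spec = full_trivariate_spec()
        th = ParameterSet(spec, np.array(draw))
        for zyg in ("MZ", "DZ"):
            mm = implied_moments(spec, th, zyg, m)
            assert np.allclose(mm.cov, mm.cov.T)
            assert np.linalg.eigvalsh(mm.cov).min() > -1e-10
            assert np.allclose(mm.cov[:3, :3], mm.cov[3:, 3:])
            assert np.allclose(mm.mean[:3], mm.mean[3:])

    @given(st.floats(0.05, 0.9), st.floats(0.0, 0.9), st.floats(0.05, 0.9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mz_cross_covariance_dominates_dz(self, a, c, e):
        # same-signed a-paths: MZ cross-twin covariance >= DZ elementwise
        th = theta_for(UNI_GRADES, {"a22": a, "c22": c, "e22": e})
        mz = implied_moments(UNI_GRADES, th, "MZ")
        dz = implied_moments(UNI_GRADES, th, "DZ")
        assert mz.cov[0, 1] >= dz.cov[0, 1] - 1e-12


class TestModelSpec:
    def test_presets_resolve_and_match_published_structure(self):
        m2d = spec_by_name("M2d")
        assert set(["b1", "b2", "b3"]) <= set(m2d.free_paths)
        assert "c33" in m2d.fixed_to_zero and "a32" in m2d.fixed_to_zero
        m3a = spec_by_name("M3a")
        assert {"ba33", "gamma32"} <= set(m3a.free_paths)
        m3b = spec_by_name("M3b")
        assert {"ba33", "gamma31"} <= set(m3b.free_paths)
        assert "gamma32" not in m3b.free_paths

    def test_json_round_trip(self):
        spec = spec_by_name("M3a_full")
        again = ModelSpec.from_json(spec.to_json())
        assert again == spec

    def test_moderation_requires_main_effect(self):
        with pytest.raises(ValueError, match="main effect"):
            ModelSpec("bad", ("iq", "grades", "exp"),
                      ("e11", "e22", "e33", "beta32", "gamma31"))

    def test_e_paths_always_free(self):
        with pytest.raises(ValueError, match="e22"):
            ModelSpec("bad", ("grades",), ("a22", "mu2"))

    def test_universe_indices_follow_phenotype_positions(self):
        uni = parameter_universe(("grades",))
        assert "a22" in uni and "a11" not in uni
        biv = parameter_universe(("grades", "exp"))
        assert "beta32" in biv and "beta21" not in biv
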