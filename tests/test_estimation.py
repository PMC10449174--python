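"""ML fitting, standard errors, likelihood-ratio tests, selection, summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from acebeta.biometric import ContractError, ModelSpec, ParameterSet, fiml_neg2ll, spec_by_name
from acebeta.estimation import (
    FitOptions,
    FitResult,
    backward_select,
    confounding_share,
    fit,
    lrt,
    model_decomposition,
    moderation_profile,
    standardized_components,
    subset_for_spec,
)
from acebeta.synthetic import GeneratorConfig, simulate_pairs

from conftest import theta_for

UNI = ModelSpec("uni", ("grades",), ("a22", "c22", "e22", "mu2"))
FAST = FitOptions(starts=2, seed=1)


def _uni_cohort(n, seed, a=0.6, c=0.4, e=0.69):
    return simulate_pairs(GeneratorConfig(
        n_pairs=n, seed=seed, theta={"a22": a, "c22": c, "e22": e}, missing_rates={}))


class TestFit:
    def test_univariate_parameter_recovery(self):
        d = _uni_cohort(2000, 21)
        r = fit(UNI, d, FAST)
        est = r.theta.as_dict()
        for name, truth in (("a22", 0.6), ("c22", 0.4), ("e22", 0.69), ("mu2", 0.0)):
            tol = max(0.05, 3.0 * (r.se_of(name) or 0.0))  # 3-SE tolerance
            assert abs(est[name] - truth) < tol, (name, est[name], tol)

    def test_ml_optimality_beats_generating_parameters(self):
        d = _uni_cohort(500, 3)
        r = fit(UNI, d, FAST, compute_se=False)
        at_truth = fiml_neg2ll(
            UNI, theta_for(UNI, {"a22": 0.6, "c22": 0.4, "e22": 0.69}), d)
        assert r.neg2ll <= at_truth + 1e-8

    def test_invariant_to_pair_order_and_twin_labels(self, rng):
        from acebeta.preprocess import PreparedData

        d = _uni_cohort(300, 5)
        r0 = fit(UNI, d, FAST, compute_se=False)
        perm = rng.permutation(d.n_pairs)
        swapped = PreparedData(
            zygosity=d.zygosity[perm], m=d.m[perm],
            y=d.y[perm][:, [3, 4, 5, 0, 1, 2]],
        )
        r1 = fit(UNI, swapped, FAST, compute_se=False)
        assert r1.neg2ll == pytest.approx(r0.neg2ll, abs=1e-6)

    def test_subset_drops_pairs_unobserved_on_phenotype(self):
        d = simulate_pairs(GeneratorConfig(n_pairs=400, seed=6,
                                           missing_rates={"grades": 0.5}))
        sub = subset_for_spec(UNI, d)
        assert sub.n_pairs < 400
        obs = ~np.isnan(sub.y[:, [1, 4]])
        assert obs.any(axis=1).all()

    def test_nesting_monotonicity_across_multivariate_sequence(self):
        d = simulate_pairs(GeneratorConfig(n_pairs=500, seed=9, missing_rates={}))
        fits = {name: fit(spec_by_name(name), d, FAST, compute_se=False)
                for name in ("M2a", "M2b", "M2c", "M2d")}
        for rich in ("M2b", "M2c", "M2d"):
            assert fits[rich].spec.nests(fits["M2a"].spec)
            assert fits[rich].neg2ll <= fits["M2a"].neg2ll + 1e-6


class TestStandardErrors:
    def test_closed_form_gaussian_limit(self):
        # residual-only model: 2n iid normals, SE(sigma) = sigma/sqrt(2N)
        spec = ModelSpec("eonly", ("grades",), ("e22", "mu2"))
        d = _uni_cohort(1000, 13, a=0.0, c=0.0, e=0.8)
        r = fit(spec, d, FAST)
        N = 2 * d.n_pairs
        closed = r.theta["e22"] / math.sqrt(2 * N)
        assert r.se_of("e22") == pytest.approx(closed, rel=0.02)

    def test_se_shrinks_with_sqrt_n(self):
        # average over a few cohorts per size: SEs are data-dependent
        ses = []
        for n in (500, 2000, 8000):
            vals = [fit(UNI, _uni_cohort(n, 30 + n + rep), FAST).se_of("a22")
                    for rep in range(3)]
            ses.append(np.mean(vals))
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.2)
        assert ses[1] / ses[2] == pytest.approx(2.0, rel=0.2)

    def test_wald_coverage(self):
        # 95% intervals should cover the generating values ~95% of the time
        truth = {"a22": 0.6, "c22": 0.4, "e22": 0.69}
        hits = total = 0
        opts = FitOptions(starts=1, seed=0)
        for rep in range(200):
            d = _uni_cohort(500, 1000 + rep)
            r = fit(UNI, d, opts)
            for name, tv in truth.items():
                se = r.se_of(name)
                if se is None:
                    continue
                total += 1
                hits += abs(r.theta[name] - tv) < 1.96 * se
        assert hits / total == pytest.approx(0.95, abs=0.04)


def _dummy_fit(spec, neg2ll, values=None):
    vals = np.zeros(spec.n_free) if values is None else values
    return FitResult(spec=spec, theta=ParameterSet(spec, vals), neg2ll=neg2ll,
                     n_pairs=1029, converged=True, n_restarts_used=1,
                     gradient_norm=0.0)


class TestLrt:
    def test_identical_fits(self):
        full = _dummy_fit(spec_by_name("M2b"), 100.0)
        restr = _dummy_fit(spec_by_name("M2a"), 100.0)
        comp = lrt(full, restr)
        assert comp.delta_neg2ll == 0.0 and comp.p_value == 1.0

    def test_published_deviance_difference(self):
        # -2LL values as printed for the no-confounding vs confounding models
        full = _dummy_fit(spec_by_name("M2b"), 15292.67)
        restr = _dummy_fit(spec_by_name("M2a"), 15311.13)
        comp = lrt(full, restr)
        assert comp.delta_neg2ll == pytest.approx(18.46, abs=1e-10)
        assert comp.df == 2
        assert comp.p_value < 0.001
        assert comp.p_value == pytest.approx(stats.chi2.sf(18.46, 2), rel=1e-10)

    def test_non_nested_is_contract_error(self):
        with pytest.raises(ContractError, match="not nested"):
            lrt(_dummy_fit(spec_by_name("M2b"), 1.0),
                _dummy_fit(spec_by_name("M2c"), 2.0))


class TestBackwardSelect:
    def test_no_op_on_strong_signal(self):
        d = _uni_cohort(2000, 41, a=0.9, c=0.7, e=0.5)
        final, trail = backward_select(UNI, d, options=FitOptions(starts=1, seed=2))
        assert final.spec.free_paths == UNI.free_paths
        for step in trail:
            assert not step["accepted"] and step["p_value"] <= 0.05

    def test_truly_zero_path_gets_fixed(self):
        # generate from an M2b-structured truth whose unique shared
        # environment on expectations is exactly zero
        theta = {"a11": 0.63, "c11": 0.48, "e11": 0.6,
                 "a22": 0.57, "c22": 0.37, "e22": 0.37,
                 "a32": 0.24, "c32": 0.23, "beta32": 0.16,
                 "a33": 0.75, "e33": 0.5}
        d = simulate_pairs(GeneratorConfig(n_pairs=2000, seed=17, theta=theta,
                                           missing_rates={}))
        start = spec_by_name("M2b").add("c33", name="M2b+c33")
        final, trail = backward_select(start, d, options=FitOptions(starts=1, seed=2))
        assert "c33" not in final.spec.free_paths
        for step in trail:
            assert step["accepted"] == (step["p_value"] > 0.05)


class TestSummaries:
    @pytest.mark.parametrize(
        "loadings,expected_a",
        [((0.56, 0.37, 0.37), 0.534), ((0.82, 0.27, 0.51), 0.669),
         ((0.63, 0.48, 0.60), 0.402), ((1.0, 0.0, 0.0), 1.0)],
    )
    def test_standardized_components(self, loadings, expected_a):
        dec = standardized_components(*loadings)
        assert dec.shares["A"] == pytest.approx(expected_a, abs=5e-4)
        assert sum(dec.shares.values()) == pytest.approx(1.0, abs=1e-8)

    def test_sign_flip_invariance(self):
        a = standardized_components(0.5, -0.3, 0.4)
        b = standardized_components(-0.5, 0.3, 0.4)
        assert a.shares == b.shares

    def test_all_zero_is_error(self):
        with pytest.raises(ContractError):
            standardized_components(0.0, 0.0, 0.0)

    def test_model_decomposition_matches_univariate_formula(self):
        th = theta_for(UNI, {"a22": 0.56, "c22": 0.37, "e22": 0.37})
        dec = model_decomposition(UNI, th, "grades")
        direct = standardized_components(0.56, 0.37, 0.37)
        for k in "ACE":
            assert dec.shares[k] == pytest.approx(direct.shares[k], abs=1e-12)

    @pytest.mark.parametrize(
        "unadj,adj,expected",
        [((0.46), 0.21, 54.3), (0.46, 0.16, 65.2), (0.37, 0.37, 0.0)],
    )
    def test_confounding_share(self, unadj, adj, expected):
        assert confounding_share(unadj, adj) == pytest.approx(expected, abs=0.05)

    def test_confounding_share_zero_denominator(self):
        with pytest.raises(ContractError):
            confounding_share(0.0, 0.1)

    def test_moderated_slope_from_published_values(self):
        spec = spec_by_name("M3a")
        th = {p: 0.0 for p in spec.free_paths}
        th.update({"beta32": 0.22, "gamma32": -0.07, "e11": 0.6, "e22": 0.4,
                   "e33": 0.5})
        f = _dummy_fit(spec, 0.0, np.array([th[p] for p in spec.free_paths]))
        prof = moderation_profile(f, m_grid=[0.0, 1.0], which="beta32")
        assert prof["slope"][0] == pytest.approx(0.22)
        assert prof["slope"][1] == pytest.approx(0.15)

    def test_unmoderated_slope_constant_with_note(self):
        spec = spec_by_name("M2d")
        th = {p: 0.0 for p in spec.free_paths}
        th.update({"beta32": 0.21, "e11": 0.6, "e22": 0.4, "e33": 0.5})
        f = _dummy_fit(spec, 0.0, np.array([th[p] for p in spec.free_paths]))
        prof = moderation_profile(f, m_grid=[-2.0, 0.0, 3.0], which="beta32")
        assert np.allclose(prof["slope"], 0.21)
        assert prof["note"] is not None

    def test_slope_linearity(self):
        spec = spec_by_name("M3a")
        th = {p: 0.0 for p in spec.free_paths}
        th.update({"beta32": 0.3, "gamma32": -0.11, "e11": 0.6, "e22": 0.4,
                   "e33": 0.5})
        f = _dummy_fit(spec, 0.0, np.array([th[p] for p in spec.free_paths]))
        prof = moderation_profile(f, m_grid=[0.0, 0.7, 1.4], which="beta32")
        s = prof["slope"]
        assert s[2] - s[0] == pytest.approx(2 * (s[1] - s[0]), abs=1e-12)
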