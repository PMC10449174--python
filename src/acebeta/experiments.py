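"""Simulation studies validating the estimator against its own oracles.

Each function runs a self-contained, seeded experiment and returns summary
statistics: moment matching of the simulator against the closed-form
implied moments, FIML against a generic Gaussian-density oracle, parameter
recovery for the fully moderated model, the type-I error of the
likelihood-ratio test, the consistency of backward selection, and the
direction of confounding-induced attenuation of the responsiveness path.

These are the package's calibration experiments; the test suite asserts
their outcomes and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import stats

from .biometric import (
    ModelSpec,
    ParameterSet,
    fiml_neg2ll,
    implied_moments,
    parameter_universe,
    spec_by_name,
)
from .estimation import FitOptions, backward_select, confounding_share, fit
from .synthetic import GeneratorConfig, default_theta, simulate_pairs

__all__ = [
    "moment_oracle_check",
    "fiml_oracle_check",
    "m3b_recovery",
    "lrt_type1",
    "selection_consistency",
    "attenuation_direction",
]

_TRI = ("iq", "grades", "exp")


def _full_spec(dz_rho: float = 0.5) -> ModelSpec:
    return ModelSpec("full", _TRI, parameter_universe(_TRI),
                     dz_genetic_correlation=dz_rho)


def _random_theta(rng: np.random.Generator) -> Dict[str, float]:
    th: Dict[str, float] = {}
    for i in (1, 2, 3):
        th[f"a{i}{i}"] = rng.uniform(0.3, 0.8)
        th[f"c{i}{i}"] = rng.uniform(0.1, 0.6)
        th[f"e{i}{i}"] = rng.uniform(0.3, 0.7)
        th[f"b{i}"] = rng.uniform(-0.3, 0.3)
        th[f"mu{i}"] = rng.uniform(-0.5, 0.5)
    for name in ("a21", "c21", "a31", "c31", "a32", "c32"):
        th[name] = rng.uniform(-0.3, 0.3)
    for name in ("beta21", "beta31", "beta32"):
        th[name] = rng.uniform(-0.2, 0.4)
    for name in ("ba31", "bc31", "gamma31", "ba32", "bc32", "gamma32",
                 "ba33", "bc33", "be33"):
        th[name] = rng.uniform(-0.15, 0.15)
    return th


def moment_oracle_check(seed: int, n_pairs: int = 250_000, n_draws: int = 5) -> Dict:
    """Empirical moments of large simulated cohorts vs implied moments.

    For each random parameter draw, zygosity and moderator level m in
    {-1, 0, 1}, simulates ``n_pairs`` pairs and standardizes every
    discrepancy by its Monte-Carlo standard error.  Returns the maximum
    |z| and the share of comparisons within 3 SEs (nominal ~99.7%).
    """
    rng = np.random.default_rng(seed)
    spec = _full_spec()
    zs = []
    for draw in range(n_draws):
        theta_map = _random_theta(rng)
        theta = ParameterSet.from_dict(spec, theta_map)
        for zyg, prop_mz in (("MZ", 1.0), ("DZ", 0.0)):
            for m in (-1.0, 0.0, 1.0):
                cfg = GeneratorConfig(
                    n_pairs=n_pairs, prop_mz=prop_mz, theta=theta_map,
                    missing_rates={}, m_fixed=m,
                    seed=int(rng.integers(2**31 - 1)),
                )
                d = simulate_pairs(cfg)
                mm = implied_moments(spec, theta, zyg, m)
                emp = np.cov(d.y, rowvar=False)
                var = np.diag(mm.cov)
                cov_se = np.sqrt((np.outer(var, var) + mm.cov**2) / n_pairs)
                iu = np.triu_indices(6)
                zs.append(((emp - mm.cov) / cov_se)[iu])
                mean_se = np.sqrt(var / n_pairs)
                zs.append((d.y.mean(axis=0) - mm.mean) / mean_se)
    z = np.abs(np.concatenate(zs))
    return {
        "max_abs_z": float(z.max()),
        "share_within_3se_pct": float(100.0 * np.mean(z <= 3.0)),
        "n_comparisons": int(z.size),
    }


def fiml_oracle_check(seed: int, n_pairs: int = 300) -> Dict:
    """FIML -2LL vs an independent multivariate-normal density computation.

    Complete-data cohorts must agree to numerical precision; a cohort with
    item missingness must agree with densities of the observed sub-vectors
    under the marginalized (row/column-dropped) implied moments.
    """
    rng = np.random.default_rng(seed)
    spec = _full_spec()
    theta = ParameterSet.from_dict(spec, _random_theta(rng))
    out = {}
    for label, rates in (("complete", {}), ("marginal", {"iq": 0.1, "grades": 0.25, "exp": 0.4})):
        cfg = GeneratorConfig(n_pairs=n_pairs, theta=theta.as_dict(),
                              missing_rates=rates, seed=seed + 1)
        d = simulate_pairs(cfg)
        keep = ~np.isnan(d.y).all(axis=1)
        d.y, d.m, d.zygosity = d.y[keep], d.m[keep], d.zygosity[keep]
        val = fiml_neg2ll(spec, theta, d)
        oracle = 0.0
        for i in range(len(d.m)):
            mm = implied_moments(spec, theta, d.zygosity[i], d.m[i])
            o = np.nonzero(~np.isnan(d.y[i]))[0]
            oracle += -2.0 * stats.multivariate_normal.logpdf(
                d.y[i, o], mm.mean[o], mm.cov[np.ix_(o, o)])
        out[f"{label}_max_abs_diff"] = abs(val - oracle)
    return out


def m3b_recovery(seed: int, n_reps: int = 100, n_pairs: int = 4000) -> Dict:
    """Bias of the fully moderated model's estimates over repeated cohorts.

    Cohorts (60% MZ, complete data) are generated at the published
    best-fitting parameters and refitted; reports the mean estimation error
    per parameter and the largest absolute bias among main paths and among
    moderation coefficients.
    """
    truth = default_theta()
    spec = spec_by_name("M3b")
    errors = {p: [] for p in spec.free_paths}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        d = simulate_pairs(GeneratorConfig(
            n_pairs=n_pairs, prop_mz=0.6, missing_rates={}, seed=rep_seed))
        r = fit(spec, d, FitOptions(starts=1, seed=rep_seed), compute_se=False)
        for p in spec.free_paths:
            errors[p].append(r.theta[p] - truth.get(p, 0.0))
    bias = {p: float(np.mean(v)) for p, v in errors.items()}
    moderation = ("ba33", "gamma31")
    return {
        "bias": bias,
        "max_abs_bias_main": max(abs(b) for p, b in bias.items() if p not in moderation),
        "max_abs_bias_moderation": max(abs(bias[p]) for p in moderation),
        "n_reps": n_reps,
        "n_pairs": n_pairs,
    }


def lrt_type1(seed: int, n_reps: int = 400, n_pairs: int = 400,
              alpha: float = 0.05) -> Dict:
    """Rejection rate of the LRT under a true restricted model.

    The tested parameter is the SES main effect on grades (b2), truly zero
    in the generating process and interior to the parameter space, so the
    statistic should be chi-square with 1 df (median ~0.455).
    """
    theta = {"a22": 0.6, "c22": 0.4, "e22": 0.69}
    null_spec = ModelSpec("null", ("grades",), ("a22", "c22", "e22", "mu2"))
    full_spec = null_spec.add("b2", name="alt")
    deltas = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        d = simulate_pairs(GeneratorConfig(
            n_pairs=n_pairs, theta=theta, missing_rates={}, seed=rep_seed))
        opts = FitOptions(starts=1, seed=rep_seed)
        f0 = fit(null_spec, d, opts, compute_se=False)
        f1 = fit(full_spec, d, opts, compute_se=False)
        deltas.append(max(f0.neg2ll - f1.neg2ll, 0.0))
    deltas = np.asarray(deltas)
    crit = stats.chi2.ppf(1 - alpha, 1)
    return {
        "rejection_rate_pct": float(100.0 * np.mean(deltas > crit)),
        "median_delta": float(np.median(deltas)),
        "n_reps": n_reps,
    }


def selection_consistency(seed: int, n_reps: int = 40, n_pairs: int = 2000,
                          alpha: float = 0.05) -> Dict:
    """How often backward selection fixes a truly zero path to zero.

    Cohorts follow a confounded bivariate-cross structure whose unique
    shared environment on expectations (c33) is exactly zero; selection
    starts from the model with c33 free.
    """
    theta = {"a22": 0.57, "c22": 0.37, "e22": 0.37,
             "a32": 0.24, "c32": 0.23, "beta32": 0.16,
             "a33": 0.75, "e33": 0.5}
    start = ModelSpec(
        "biv+c33", ("grades", "exp"),
        ("a22", "c22", "e22", "a32", "c32", "beta32",
         "a33", "c33", "e33", "mu2", "mu3"),
    )
    fixed = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        d = simulate_pairs(GeneratorConfig(
            n_pairs=n_pairs, theta=theta, missing_rates={}, seed=rep_seed))
        final, _ = backward_select(start, d, alpha,
                                   FitOptions(starts=1, seed=rep_seed))
        fixed += "c33" not in final.spec.free_paths
    return {"c33_fixed_pct": float(100.0 * fixed / n_reps), "n_reps": n_reps}


def attenuation_direction(seed: int, n_pairs: int = 4000) -> Dict:
    """Confounding-induced shrinkage of the responsiveness path.

    Under the published generating process (shared genetic and
    environmental influences on both performance and expectations), the
    uncontrolled responsiveness estimate (no-confounding model) must exceed
    the estimate that models the latent confounders and SES.
    """
    d = simulate_pairs(GeneratorConfig(n_pairs=n_pairs, missing_rates={}, seed=seed))
    opts = FitOptions(starts=2, seed=seed)
    fa = fit(spec_by_name("M2a"), d, opts, compute_se=False)
    fd = fit(spec_by_name("M2d"), d, opts, compute_se=False)
    b_un, b_adj = fa.theta["beta32"], fd.theta["beta32"]
    return {
        "beta32_unadjusted": float(b_un),
        "beta32_adjusted": float(b_adj),
        "share_pct": float(confounding_share(b_un, b_adj)),
        "n_pairs": n_pairs,
    }
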