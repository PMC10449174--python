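"""Synthetic MZ/DZ twin cohorts from the moderated ACE-beta structural model.

The generator draws, per family, a standard-normal moderator ``m``
(standardized parental education), unit-variance latent A/C/E factors with
the usual cross-twin correlations (A: 1 for MZ, ``dz_genetic_correlation``
for DZ; C: 1; E: 0), and computes cognitive ability, grades and
expectations from the same structural equations that
:mod:`acebeta.biometric` uses for the implied moments -- so empirical
moments of a large cohort are a direct Monte-Carlo oracle for
:func:`acebeta.biometric.implied_moments`.

:func:`simulate_pairs` returns the latent-phenotype cohort as
:class:`~acebeta.preprocess.PreparedData` (the object every likelihood
consumes); :func:`simulate_raw_survey` additionally maps the latent
phenotypes back to raw survey columns (grades 1-6, aspiration and success
probability, CFT subscale sums, sex/age/school type, parental years of
education) so the whole preprocessing pipeline can be exercised without
external data.

Default cohort conditions mimic the German twin survey the design targets:
1029 pairs, balanced zygosity groups, missingness about 33% for
expectations, 18% for grades and 1.3% for cognitive ability, and
best-fitting published path coefficients as the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .biometric import (
    ContractError,
    ModelSpec,
    ParameterSet,
    parameter_universe,
    _reduced_form,
    _values_full,
)
from .preprocess import PreparedData
from .twin_data import TwinObservation, TwinPairRecord, TwinPairTable

__all__ = ["GeneratorConfig", "default_theta", "simulate_pairs", "simulate_raw_survey"]

#: generating parameters: the published best-fitting moderated model
_DEFAULT_THETA = {
    "a11": 0.62, "c11": 0.38, "e11": 0.61,
    "a21": 0.23, "beta21": 0.11,
    "a22": 0.48, "c22": 0.28, "e22": 0.37,
    "a31": 0.31, "beta31": 0.09, "beta32": 0.21,
    "a33": 0.66, "e33": 0.50,
    "b1": 0.32, "b2": 0.20, "b3": 0.30,
    "ba33": -0.09, "gamma31": -0.08,
}


def default_theta() -> Dict[str, float]:
    return dict(_DEFAULT_THETA)


@dataclass
class GeneratorConfig:
    """Conditions of a simulated twin cohort."""

    n_pairs: int = 1029
    prop_mz: float = 0.5
    theta: Dict[str, float] = field(default_factory=default_theta)
    dz_genetic_correlation: float = 0.5
    missing_rates: Dict[str, float] = field(
        default_factory=lambda: {"iq": 0.013, "grades": 0.18, "exp": 0.33}
    )
    #: MAR hook: per-phenotype logit shift of the missingness probability
    #: per unit of m; all zero -> MCAR (the default).
    mar_slopes: Dict[str, float] = field(default_factory=dict)
    #: fix the moderator at one value instead of drawing N(0,1)
    m_fixed: Optional[float] = None
    raw_survey: bool = False
    seed: int = 0
    # --- raw-survey mapping knobs ---
    raw_noise: float = 0.3  # SD of noise added when mapping latents to raw items
    sex_effects: Dict[str, float] = field(
        default_factory=lambda: {"iq": 0.0, "grades": 0.25, "exp": 0.1}
    )
    age_effects: Dict[str, float] = field(
        default_factory=lambda: {"iq": 0.3, "grades": 0.0, "exp": 0.0}
    )

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ContractError("n_pairs must be >= 1")
        if not 0.0 <= self.prop_mz <= 1.0:
            raise ContractError("prop_mz must be in [0, 1]")
        for k, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise ContractError(f"missing rate for {k} must be in [0, 1), got {r}")
        universe = parameter_universe(("iq", "grades", "exp"))
        unknown = set(self.theta) - set(universe)
        if unknown:
            raise ContractError(f"unknown theta entries: {sorted(unknown)}")
        for e in ("e11", "e22", "e33"):
            if self.theta.get(e, 0.0) < 0.0:
                raise ContractError(f"{e} must be non-negative in theta")


def _sim_spec(config: GeneratorConfig) -> ModelSpec:
    universe = parameter_universe(("iq", "grades", "exp"))
    free = tuple(
        p for p in universe
        if config.theta.get(p, 0.0) != 0.0 or p.startswith("e") or p.startswith("mu")
    )
    return ModelSpec(
        "generator", ("iq", "grades", "exp"), free,
        dz_genetic_correlation=config.dz_genetic_correlation,
    )


def _latent_phenotypes(config: GeneratorConfig, rng: np.random.Generator):
    """Draw latents and compute the (n, 6) phenotype matrix plus m, zygosity."""
    n = config.n_pairs
    n_mz = int(round(n * config.prop_mz))
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * (n - n_mz))
    is_mz = zyg == "MZ"
    if config.m_fixed is None:
        m = rng.standard_normal(n)
    else:
        m = np.full(n, float(config.m_fixed))

    spec = _sim_spec(config)
    theta = ParameterSet.from_dict(spec, {k: v for k, v in config.theta.items() if k in spec.free_paths})
    vals = _values_full(spec, theta)
    _, Lam, eta, _ = _reduced_form(spec, vals, m, is_mz)

    p = 3
    rho = np.where(is_mz, 1.0, config.dz_genetic_correlation)
    a1 = rng.standard_normal((n, p))
    a2 = rho[:, None] * a1 + np.sqrt(1.0 - rho[:, None] ** 2) * rng.standard_normal((n, p))
    c = rng.standard_normal((n, p))  # shared within family
    e1 = rng.standard_normal((n, p))
    e2 = rng.standard_normal((n, p))
    lat1 = np.concatenate([a1, c, e1], axis=1)
    lat2 = np.concatenate([a2, c, e2], axis=1)
    y1 = eta + np.einsum("nij,nj->ni", Lam, lat1)
    y2 = eta + np.einsum("nij,nj->ni", Lam, lat2)
    y = np.concatenate([y1, y2], axis=1)  # IQ1, Grades1, Exp1, IQ2, Grades2, Exp2
    return y, m, zyg


def _missing_mask(config: GeneratorConfig, m: np.ndarray, rng: np.random.Generator):
    """(n, 6) boolean mask, True = set missing. MCAR, or MAR in m via the hook."""
    n = len(m)
    mask = np.zeros((n, 6), dtype=bool)
    for q, pheno in enumerate(("iq", "grades", "exp")):
        rate = config.missing_rates.get(pheno, 0.0)
        if rate <= 0.0:
            continue
        slope = config.mar_slopes.get(pheno, 0.0)
        if slope == 0.0:
            prob = np.full(n, rate)
        else:
            logit = np.log(rate / (1.0 - rate)) + slope * m
            prob = 1.0 / (1.0 + np.exp(-logit))
        for t in (0, 1):
            mask[:, 3 * t + q] = rng.random(n) < prob
    return mask


def simulate_pairs(config: GeneratorConfig) -> PreparedData:
    """Simulate a latent-phenotype twin cohort; reproducible under the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    y, m, zyg = _latent_phenotypes(config, rng)
    y = y.copy()
    y[_missing_mask(config, m, rng)] = np.nan
    return PreparedData(
        zygosity=zyg,
        m=m,
        y=y,
        family_ids=[f"F{i:05d}" for i in range(config.n_pairs)],
        provenance={"generator": "simulate_pairs", "seed": config.seed, "theta": dict(config.theta)},
    )


# ---------------------------------------------------------------------------
# raw-survey mapping (inverse of the preprocessing pipeline, approximately)

_CFT_MEANS = (9.0, 9.0, 9.0, 7.0)
_CFT_LOADINGS = (2.2, 2.2, 2.2, 1.6)
_CFT_MAXIMA = (15.0, 15.0, 15.0, 11.0)
_SCHOOL_OFFSET = {"low": 0.5, "mid": 0.0, "high": -0.5}


def simulate_raw_survey(config: GeneratorConfig, return_latents: bool = False):
    """Simulate a raw-survey twin table (grades, aspiration/success, CFT, ...).

    Latent phenotypes from the structural model are mapped to raw survey
    items: cognitive ability to four CFT subscale sums, grades to 1-6 Math
    and German grades with school-type offsets, expectations to an
    aspiration level and a success probability whose product reproduces the
    latent score.  Sex and age effects are added before mapping so the
    residualization step of :func:`acebeta.preprocess.prepare` is exercised;
    ``raw_noise`` scales item noise (0 gives the deterministic mapping).
    Missingness is applied to the raw items at the configured rates.

    With ``return_latents=True`` also returns the generating latent
    :class:`~acebeta.preprocess.PreparedData` (no missingness applied).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    y, m, zyg = _latent_phenotypes(config, rng)
    n = config.n_pairs
    latents = PreparedData(
        zygosity=zyg, m=m.copy(), y=y.copy(),
        family_ids=[f"F{i:05d}" for i in range(n)],
        provenance={"generator": "simulate_raw_survey", "seed": config.seed,
                    "theta": dict(config.theta)},
    )

    sex = np.where(rng.random(n) < 0.5, "female", "male")  # same-sex pairs
    age = np.clip(np.round(rng.normal(11.0, 0.32, size=n), 1), 10.0, 12.0)
    par_edu = np.round(14.0 + 2.8 * m, 1)

    # add observed-covariate effects to the latent phenotypes
    y = y.copy()
    for q, pheno in enumerate(("iq", "grades", "exp")):
        shift = config.sex_effects.get(pheno, 0.0) * (sex == "female") + \
            config.age_effects.get(pheno, 0.0) * (age - 11.0)
        y[:, q] += shift
        y[:, 3 + q] += shift

    # school track follows family SES plus an independent lottery, so the
    # grading offsets can be residualized away without destroying the
    # latent grade signal
    fam_track = 0.5 * m + rng.standard_normal(n)
    school = np.where(fam_track < -0.6, "low", np.where(fam_track < 0.6, "mid", "high"))

    mask = _missing_mask(config, m, rng)
    noise = config.raw_noise

    records = []
    for i in range(n):
        twins = []
        for t in (0, 1):
            iq_l, g_l, x_l = y[i, 3 * t], y[i, 3 * t + 1], y[i, 3 * t + 2]
            obs = TwinObservation(sex=str(sex[i]), age=float(age[i]), school_type=str(school[i]))
            if not mask[i, 3 * t + 0]:
                for j in range(4):
                    v = _CFT_MEANS[j] + _CFT_LOADINGS[j] * iq_l + noise * rng.standard_normal()
                    setattr(obs, f"cft{j+1}", float(np.clip(np.round(v), 0, _CFT_MAXIMA[j])))
            if not mask[i, 3 * t + 1]:
                off = _SCHOOL_OFFSET[str(school[i])]
                # subject-difficulty offsets stagger the two rounding grids,
                # so the two-subject average resolves half-grade steps
                for subj, diff in (("grade_math", 0.25), ("grade_german", -0.25)):
                    g = 3.5 + diff - 1.5 * g_l + off + noise * rng.standard_normal()
                    setattr(obs, subj, float(np.clip(np.round(g), 1, 6)))
            if not mask[i, 3 * t + 2]:
                asp = int(1 + (x_l >= -0.5) + (x_l >= 0.5))
                succ = 100.0 * (1.5 + 0.5 * x_l) / asp + noise * rng.standard_normal()
                obs.aspiration = asp
                obs.success_prob = float(np.clip(np.round(succ), 0, 100))
            twins.append(obs)
        records.append(
            TwinPairRecord(
                family_id=f"F{i:05d}", zygosity=str(zyg[i]),
                twin1=twins[0], twin2=twins[1], par_edu_years=float(par_edu[i]),
            )
        )
    table = TwinPairTable(records=records, source="simulate_raw_survey", layout="wide")
    if return_latents:
        return table, latents
    return table
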