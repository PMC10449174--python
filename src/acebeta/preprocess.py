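"""Construction of the analysis phenotypes and the SES moderator.

The three phenotypes are, per twin:

* **expectations** -- the desired school-leaving qualification (1 lower,
  2 intermediate, 3 higher) weighted by the perceived probability of
  attaining it: ``score = aspiration * success_prob / 100``;
* **grades** -- the mean of reverse-coded (``7 - g``) Math and German
  grades, residualized for school type so that tracks are comparable;
* **iq** -- a single-factor CFA score over the four CFT subscale sums.

All three are residualized for sex and age (pooling both twins of every
pair in one regression), then standardized to mean 0 / variance 1 pooled
over twins.  The family-level moderator is standardized parental years of
education; pairs with a missing moderator are listwise deleted, and a pair
is retained only if it has at least one non-missing phenotype entry
(FIML handles the rest of the missingness).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .twin_data import DataError, TwinPairTable

__all__ = [
    "PrepConfig",
    "PreparedData",
    "CfaConvergenceError",
    "expectation_score",
    "average_reversed_grade",
    "cfa_ability_score",
    "residualize",
    "prepare",
    "save_prepared",
    "load_prepared",
]

_PREPARED_COLUMNS = ["iq_1", "grades_1", "exp_1", "iq_2", "grades_2", "exp_2"]


class CfaConvergenceError(RuntimeError):
    """The single-factor ML fit did not converge; carries the iteration log."""


@dataclass
class PrepConfig:
    """Tunable preprocessing choices.

    ``expectation_formula`` is a hook: any callable ``(aspiration,
    success_prob) -> float``; the default multiplies the aspiration level by
    the success probability on [0, 1].
    """

    expectation_formula: Optional[Callable[[float, float], float]] = None
    grade_reversal_constant: float = 7.0
    school_type_reference: Optional[str] = None  # None -> modal category
    standardize: bool = True
    cfa_max_iter: int = 500
    cfa_tol: float = 1e-10


@dataclass
class PreparedData:
    """Analysis-ready twin-pair data.

    ``y`` columns are (IQ1, Grades1, Exp1, IQ2, Grades2, Exp2) with NaN for
    missing entries; ``m`` is the complete, standardized family-level
    moderator.
    """

    zygosity: np.ndarray  # (n,) of "MZ"/"DZ"
    m: np.ndarray  # (n,)
    y: np.ndarray  # (n, 6)
    family_ids: list = field(default_factory=list)
    provenance: Dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.m)


def expectation_score(aspiration, success_prob, formula=None):
    """Raw expectation score: aspiration level weighted by success probability.

    Returns NaN if either input is missing; raises for out-of-range inputs.
    """
    if aspiration is None or (isinstance(aspiration, float) and math.isnan(aspiration)):
        return float("nan")
    if success_prob is None or (isinstance(success_prob, float) and math.isnan(success_prob)):
        return float("nan")
    if int(aspiration) not in (1, 2, 3):
        raise DataError(f"aspiration {aspiration!r} not in {{1,2,3}}")
    if not 0.0 <= float(success_prob) <= 100.0:
        raise DataError(f"success_prob {success_prob!r} outside [0, 100]")
    if formula is not None:
        return float(formula(aspiration, success_prob))
    return float(aspiration) * float(success_prob) / 100.0


def average_reversed_grade(grade_math, grade_german, reversal_constant: float = 7.0):
    """Mean of reverse-coded grades so that higher = better performance.

    German grades run 1 (best) to 6 (worst); ``7 - g`` keeps the 1-6 range.
    If one subject is missing the other is used alone; both missing -> NaN.
    """
    vals = []
    for g in (grade_math, grade_german):
        if g is None or (isinstance(g, float) and math.isnan(g)):
            continue
        if not 1.0 <= float(g) <= 6.0:
            raise DataError(f"grade {g!r} outside [1, 6]")
        vals.append(reversal_constant - float(g))
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def _fit_single_factor(S: np.ndarray, max_iter: int, tol: float):
    """ML single-factor fit of a covariance matrix: loadings and uniquenesses."""
    k = S.shape[0]
    diag = np.diag(S)
    x0 = np.concatenate([np.sqrt(0.5 * diag), 0.5 * diag])
    log = []

    def objective(x):
        lam, psi = x[:k], x[k:]
        Sigma = np.outer(lam, lam) + np.diag(psi)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e10
        val = logdet + float(np.trace(np.linalg.solve(Sigma, S)))
        log.append(val)
        return val

    bounds = [(None, None)] * k + [(1e-6, None)] * k  # Heywood guard
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol},
    )
    if not res.success and res.status != 0:
        raise CfaConvergenceError(
            f"single-factor ML did not converge: {res.message}; "
            f"objective trace (last 10): {log[-10:]}"
        )
    lam, psi = res.x[:k], res.x[k:]
    if np.any(psi <= 2e-6):
        warnings.warn("Heywood case: unique variance bounded at 1e-6")
    if lam.sum() < 0:  # loadings identified up to sign
        lam = -lam
    return lam, psi


def cfa_ability_score(cft: pd.DataFrame, max_iter: int = 500, tol: float = 1e-10):
    """Single-factor CFA over the four CFT subscale sums; regression scores.

    The factor model (4 loadings, 4 unique variances) is fitted by ML on the
    observed covariance of complete cases.  Regression-method factor scores
    are computed for every twin with at least one observed indicator, using
    that twin's observed subset, and standardized to mean 0 / variance 1.
    Returns ``(scores, info)`` where ``info`` holds loadings and uniquenesses.
    """
    X = np.asarray(cft, dtype=float)
    n, k = X.shape
    obs = ~np.isnan(X)
    if (obs.sum(axis=1) >= 3).sum() < 50:
        raise DataError("need at least 50 twins with >= 3 non-missing CFT subscales")
    complete = obs.all(axis=1)
    Xc = X[complete]
    mean = Xc.mean(axis=0)
    S = np.cov(Xc, rowvar=False)
    if np.allclose(S, S[0, 0] * np.ones_like(S)):
        # collinear limit: all indicators identical -> score is the indicator
        z = (X[:, 0] - np.nanmean(X[:, 0])) / np.nanstd(X[:, 0])
        scores = np.where(obs.any(axis=1), z, np.nan)
        return scores, {"loadings": None, "uniquenesses": None, "degenerate": True}
    lam, psi = _fit_single_factor(S, max_iter, tol)
    Sigma = np.outer(lam, lam) + np.diag(psi)
    scores = np.full(n, np.nan)
    for pattern in np.unique(obs[obs.any(axis=1)], axis=0):
        o = np.nonzero(pattern)[0]
        sel = np.nonzero((obs == pattern).all(axis=1))[0]
        if sel.size == 0:
            continue
        w = np.linalg.solve(Sigma[np.ix_(o, o)], lam[o])
        scores[sel] = (X[np.ix_(sel, o)] - mean[o]) @ w
    ok = ~np.isnan(scores)
    scores[ok] = (scores[ok] - scores[ok].mean()) / scores[ok].std()
    return scores, {"loadings": lam, "uniquenesses": psi, "degenerate": False}


def _design_matrix(covariates: pd.DataFrame, reference: Optional[Dict[str, str]] = None):
    """Intercept + dummy-coded categorical / numeric columns."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            ref = (reference or {}).get(col)
            if ref is None:
                ref = s.mode().iloc[0]  # modal category as reference
            dummies = pd.get_dummies(s, prefix=col, dtype=float)
            ref_col = f"{col}_{ref}"
            if ref_col in dummies:
                dummies = dummies.drop(columns=ref_col)
            parts.append(dummies)
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


def residualize(values, covariates: pd.DataFrame, reference: Optional[Dict[str, str]] = None):
    """OLS residuals of *values* on *covariates* (intercept included).

    Rows with missing value propagate NaN.  Covariates must be complete on
    rows where the value is observed.  A rank-deficient design drops aliased
    columns with a warning.  Returns ``(residuals, coefficients)``.
    """
    v = np.asarray(values, dtype=float)
    X = _design_matrix(covariates, reference)
    Xv = np.asarray(X, dtype=float)
    ok = ~np.isnan(v)
    if not ok.any():
        raise DataError("residualize needs at least one non-missing value")
    if np.isnan(Xv[ok]).any():
        raise DataError("covariates must be complete on rows with observed values")
    Xo, vo = Xv[ok], v[ok]
    rank = np.linalg.matrix_rank(Xo)
    cols = list(X.columns)
    if rank < Xo.shape[1]:
        keep = []
        for j in range(Xo.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(Xo[:, trial]) == len(trial):
                keep.append(j)
        dropped = [cols[j] for j in range(Xo.shape[1]) if j not in keep]
        warnings.warn(f"rank-deficient design; dropping aliased columns {dropped}")
        Xo = Xo[:, keep]
        Xv = Xv[:, keep]
        cols = [cols[j] for j in keep]
    beta, *_ = np.linalg.lstsq(Xo, vo, rcond=None)
    resid = np.full_like(v, np.nan)
    resid[ok] = vo - Xo @ beta
    return resid, dict(zip(cols, beta.tolist()))


def _standardize(x: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(x)
    mu = x[ok].mean()
    sd = x[ok].std()
    if sd == 0:
        raise DataError("cannot standardize a constant column")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - mu) / sd
    return out


def prepare(table: TwinPairTable, config: Optional[PrepConfig] = None) -> PreparedData:
    """Run the full preprocessing pipeline on a raw twin-pair table.

    Pipeline: expectation score -> reversed-grade average -> CFA ability
    score -> residualize grades on school type -> residualize all three
    phenotypes on sex and age -> drop pairs with missing moderator, then
    pairs with zero non-missing phenotypes -> standardize phenotypes
    (pooled over twins) and the moderator over retained pairs.  Drop counts
    and regression coefficients are reported in ``provenance``.
    """
    config = config or PrepConfig()
    table.validate()
    df = table.to_long_frame()
    if df.empty:
        raise DataError("empty table")
    prov: Dict = {"n_pairs_in": table.n_pairs}

    exp_raw = np.array(
        [
            rowv if rowv is not None and not (isinstance(rowv, float) and math.isnan(rowv))
            else expectation_score(a, s, config.expectation_formula)
            for rowv, a, s in zip(df["expectation_raw"], df["aspiration"], df["success_prob"])
        ],
        dtype=float,
    )
    grades_raw = np.array(
        [
            average_reversed_grade(gm, gg, config.grade_reversal_constant)
            for gm, gg in zip(df["grade_math"], df["grade_german"])
        ],
        dtype=float,
    )
    iq_raw, cfa_info = cfa_ability_score(
        df[["cft1", "cft2", "cft3", "cft4"]], config.cfa_max_iter, config.cfa_tol
    )
    prov["cfa"] = {
        "loadings": None if cfa_info["loadings"] is None else cfa_info["loadings"].tolist(),
        "degenerate": cfa_info["degenerate"],
    }

    # grades: school-type residualization (observed grades need school type)
    st_missing = df["school_type"].isna() & ~np.isnan(grades_raw)
    if st_missing.any():
        grades_raw[st_missing.values] = np.nan
        prov["n_grades_masked_missing_school_type"] = int(st_missing.sum())
    if (~np.isnan(grades_raw)).any() and df["school_type"].notna().any():
        ref = (
            {"school_type": config.school_type_reference}
            if config.school_type_reference
            else None
        )
        grades_raw, coef = residualize(grades_raw, df[["school_type"]], ref)
        prov["school_type_coefficients"] = coef

    # sex/age residualization, pooling all twins in one regression
    covs = pd.DataFrame(
        {
            "female": (df["sex"] == "female").astype(float).where(df["sex"].notna()),
            "age": pd.to_numeric(df["age"]),
        }
    )
    prov["residualization"] = {}
    phenos = {"iq": iq_raw, "grades": grades_raw, "exp": exp_raw}
    for name, vec in phenos.items():
        mask = np.isnan(np.asarray(covs, dtype=float)).any(axis=1) & ~np.isnan(vec)
        if mask.any():
            vec = vec.copy()
            vec[mask] = np.nan
            prov.setdefault("n_masked_missing_sex_age", {})[name] = int(mask.sum())
        resid, coef = residualize(vec, covs)
        phenos[name] = resid
        prov["residualization"][name] = coef

    # assemble one row per pair
    wide = {}
    for name, vec in phenos.items():
        tmp = pd.DataFrame({"family_id": df["family_id"], "ptyp": df["ptyp"], name: vec})
        wide[name] = tmp.pivot(index="family_id", columns="ptyp", values=name)
    fam = df.drop_duplicates("family_id").set_index("family_id")
    order = df["family_id"].drop_duplicates().tolist()

    y_cols = []
    for t in (1, 2):
        for name in ("iq", "grades", "exp"):
            col = wide[name][t] if t in wide[name].columns else pd.Series(np.nan, index=fam.index)
            y_cols.append(col.reindex(order).to_numpy(dtype=float))
    y = np.column_stack(y_cols)  # (n, 6): IQ1, Grades1, Exp1, IQ2, Grades2, Exp2
    m = pd.to_numeric(fam["par_edu_years"]).reindex(order).to_numpy(dtype=float)
    zyg = fam["zygosity"].reindex(order).to_numpy()

    keep_m = ~np.isnan(m)
    prov["n_dropped_missing_moderator"] = int((~keep_m).sum())
    keep_ph = ~np.isnan(y).all(axis=1)
    prov["n_dropped_no_phenotype"] = int((keep_m & ~keep_ph).sum())
    keep = keep_m & keep_ph
    if not keep.any():
        raise DataError("no pairs left after dropping missing moderator / empty phenotypes")
    y, m, zyg = y[keep], m[keep], zyg[keep]
    ids = [fid for fid, k in zip(order, keep) if k]
    prov["n_pairs_out"] = int(keep.sum())

    if config.standardize:
        for q in range(3):
            both = np.concatenate([y[:, q], y[:, 3 + q]])
            both = _standardize(both)
            y[:, q], y[:, 3 + q] = both[: len(y)], both[len(y):]
        m = _standardize(m)

    return PreparedData(zygosity=zyg, m=m, y=y, family_ids=ids, provenance=prov)


def save_prepared(data: PreparedData, path) -> None:
    """Write analysis-ready data as a flat CSV (one row per pair)."""
    df = pd.DataFrame(
        {"family_id": data.family_ids or [f"F{i:05d}" for i in range(data.n_pairs)],
         "zygosity": data.zygosity, "m": data.m},
    )
    for j, col in enumerate(_PREPARED_COLUMNS):
        df[col] = data.y[:, j]
    df.to_csv(path, index=False, float_format="%.12g")


def load_prepared(path) -> PreparedData:
    """Read a CSV written by :func:`save_prepared`."""
    df = pd.read_csv(path)
    missing = [c for c in ["family_id", "zygosity", "m", *_PREPARED_COLUMNS] if c not in df]
    if missing:
        raise DataError(f"{path}: missing prepared-data columns {missing}")
    return PreparedData(
        zygosity=df["zygosity"].to_numpy(),
        m=df["m"].to_numpy(dtype=float),
        y=df[_PREPARED_COLUMNS].to_numpy(dtype=float),
        family_ids=df["family_id"].astype(str).tolist(),
        provenance={"source": str(path)},
    )
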