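"""Maximum-likelihood fitting and model comparison for twin SEMs.

Fitting minimizes the FIML -2 log-likelihood with L-BFGS-B using the
analytic gradient, from several jittered starting points (the likelihood
has sign-symmetric and occasionally flat regions).  Standard errors come
from the observed information: ``SE = sqrt(diag(2 H^{-1}))`` with ``H`` the
numerical Hessian of -2LL at the optimum (central differences of the
analytic gradient).  Nested models are compared by likelihood-ratio tests
against the chi-square reference; for variance loadings tested at zero this
reference is conservative (the usual boundary caveat), which matches common
twin-model practice.

``backward_select`` reproduces the "parameters could be fixed to 0"
reporting style deterministically: it repeatedly tries to fix the least
significant eligible path (smallest |estimate|/SE) and keeps the fixation
whenever the LRT does not reject it.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .biometric import (
    MODERATION_MAP,
    ContractError,
    ModelSpec,
    ParameterSet,
    _INDEX,
    _MAIN_TO_MOD,
    _data_columns,
    fiml_neg2ll,
)
from .preprocess import PreparedData

__all__ = [
    "EstimationError",
    "FitOptions",
    "FitResult",
    "ComparisonResult",
    "VarianceDecomposition",
    "subset_for_spec",
    "fit",
    "standard_errors",
    "lrt",
    "backward_select",
    "standardized_components",
    "model_decomposition",
    "confounding_share",
    "moderation_profile",
]


class EstimationError(RuntimeError):
    pass


@dataclass
class FitOptions:
    starts: int = 10
    seed: int = 20230824
    jitter_sd: float = 0.2
    max_iter: int = 2000
    grad_tol: float = 1e-4  # inf-norm defining "converged"
    start_values: Optional[Dict[str, float]] = None


@dataclass
class FitResult:
    spec: ModelSpec
    theta: ParameterSet
    neg2ll: float
    n_pairs: int
    converged: bool
    n_restarts_used: int
    gradient_norm: float
    se: Optional[np.ndarray] = None
    data_fingerprint: str = ""

    @property
    def aic(self) -> float:
        return self.neg2ll + 2.0 * self.spec.n_free

    def se_of(self, name: str) -> Optional[float]:
        if self.se is None:
            return None
        v = self.se[self.spec.free_paths.index(name)]
        return None if np.isnan(v) else float(v)

    def z_values(self) -> Dict[str, float]:
        if self.se is None:
            raise EstimationError("standard errors not computed")
        out = {}
        for i, name in enumerate(self.spec.free_paths):
            s = self.se[i]
            out[name] = float(abs(self.theta.values[i]) / s) if s and not np.isnan(s) else np.inf
        return out


@dataclass
class ComparisonResult:
    delta_neg2ll: float
    df: int
    p_value: float
    preferred: str
    full_name: str = ""
    restricted_name: str = ""


@dataclass
class VarianceDecomposition:
    """Standardized A/C/E variance shares for one phenotype (sum to 1)."""

    shares: Dict[str, float]

    def as_percent(self, ndigits: int = 0) -> Dict[str, float]:
        return {k: round(100.0 * v, ndigits) for k, v in self.shares.items()}


# ---------------------------------------------------------------------------


def _fingerprint(data: PreparedData) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(data.y).tobytes())
    h.update(np.ascontiguousarray(data.m).tobytes())
    h.update("".join(map(str, data.zygosity)).encode())
    return h.hexdigest()[:16]


def subset_for_spec(spec: ModelSpec, data: PreparedData) -> PreparedData:
    """Drop pairs with zero observed entries on the spec's phenotypes.

    This mirrors FIML's "at least one non-missing value" rule per model, so
    univariate models use only pairs observed on that phenotype.
    """
    cols = _data_columns(spec)
    keep = ~np.isnan(np.asarray(data.y, dtype=float)[:, cols]).all(axis=1)
    return PreparedData(
        zygosity=np.asarray(data.zygosity)[keep],
        m=np.asarray(data.m, dtype=float)[keep],
        y=np.asarray(data.y, dtype=float)[keep],
        family_ids=[f for f, k in zip(data.family_ids, keep) if k] if data.family_ids else [],
        provenance={"subset_for": spec.name, "n_dropped": int((~keep).sum())},
    )


def _default_start(spec: ModelSpec, data: PreparedData) -> np.ndarray:
    y = np.asarray(data.y, dtype=float)
    start = np.zeros(spec.n_free)
    for i, name in enumerate(spec.free_paths):
        if name[0] in "ace" and len(name) == 3 and name[1] == name[2]:
            start[i] = 0.5
        elif name.startswith("mu"):
            q = ("iq", "grades", "exp").index(
                {1: "iq", 2: "grades", 3: "exp"}[int(name[-1])]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mval = np.nanmean(np.concatenate([y[:, q], y[:, 3 + q]]))
            start[i] = 0.0 if np.isnan(mval) else mval
    return start


def _bounds(spec: ModelSpec) -> list:
    bounds = []
    for name in spec.free_paths:
        if name[0] == "e" and len(name) == 3:  # e11, e22, e33
            bounds.append((1e-6, None))
        else:
            bounds.append((None, None))
    return bounds


def _canonical_signs(spec: ModelSpec, values: np.ndarray) -> np.ndarray:
    """Flip latent-factor signs so diagonal loadings are non-negative.

    Flipping factor k negates every loading on it (diagonal, cross-loadings
    and their moderation coefficients) and leaves the likelihood unchanged.
    """
    out = values.copy()
    names = spec.free_paths
    for kind in ("a", "c"):
        for k in (1, 2, 3):
            diag = f"{kind}{k}{k}"
            if diag not in names:
                continue
            if out[names.index(diag)] >= 0:
                continue
            for i in (k, k + 1, k + 2):
                for nm in (f"{kind}{i}{k}", _MAIN_TO_MOD.get(f"{kind}{i}{k}", "")):
                    if nm in names:
                        out[names.index(nm)] *= -1.0
    # e-paths are bounded positive already; be33 follows e33's sign convention
    return out


def fit(
    spec: ModelSpec,
    data: PreparedData,
    options: Optional[FitOptions] = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit *spec* to *data* by FIML from multiple jittered starts.

    The best converged solution (lowest -2LL, gradient inf-norm below
    ``grad_tol``) wins; if no start converges an :class:`EstimationError`
    with per-start diagnostics is raised.
    """
    options = options or FitOptions()
    sub = subset_for_spec(spec, data)
    if sub.n_pairs == 0:
        raise EstimationError(f"no usable pairs for spec {spec.name}")

    def objective(x):
        return fiml_neg2ll(spec, ParameterSet(spec, x), sub, return_grad=True)

    rng = np.random.default_rng(options.seed)
    base = (
        np.array([options.start_values.get(p, 0.0) for p in spec.free_paths])
        if options.start_values is not None
        else _default_start(spec, sub)
    )
    bounds = _bounds(spec)
    attempts = []
    for s in range(options.starts):
        x0 = base if s == 0 else base + rng.normal(0.0, options.jitter_sd, size=spec.n_free)
        x0 = np.clip(x0, [b[0] if b[0] is not None else -np.inf for b in bounds], np.inf)
        lbfgs_opts = {
            "maxiter": options.max_iter, "ftol": 0.0, "gtol": 1e-8,
            "maxcor": 30, "maxls": 60,
        }
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options=lbfgs_opts,
        )
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        if gnorm >= options.grad_tol and np.isfinite(res.fun):
            # restart once: resetting the Hessian approximation often
            # squeezes the last orders of magnitude out of the gradient
            res2 = optimize.minimize(
                objective, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
                options=lbfgs_opts,
            )
            g2 = float(np.max(np.abs(res2.jac))) if res2.jac is not None else np.inf
            if res2.fun <= res.fun or g2 < gnorm:
                res, gnorm = res2, g2
        attempts.append((float(res.fun), gnorm, res.x, res.message))
    converged = [(f, g, x) for f, g, x, _ in attempts if g < options.grad_tol and f < 1e11]
    if converged:
        fbest, gbest, xbest = min(converged, key=lambda t: t[0])
        ok = True
    else:
        usable = [(f, g, x) for f, g, x, _ in attempts if f < 1e11]
        if not usable:
            diag = "; ".join(f"start {i}: f={f:.3g} |g|={g:.3g} ({msg})"
                             for i, (f, g, _, msg) in enumerate(attempts))
            raise EstimationError(f"no start converged for {spec.name}: {diag}")
        fbest, gbest, xbest = min(usable, key=lambda t: t[0])
        ok = False
    xbest = _canonical_signs(spec, xbest)
    result = FitResult(
        spec=spec,
        theta=ParameterSet(spec, xbest),
        neg2ll=fbest,
        n_pairs=sub.n_pairs,
        converged=ok,
        n_restarts_used=len(attempts),
        gradient_norm=gbest,
        data_fingerprint=_fingerprint(data),
    )
    if compute_se:
        result.se = standard_errors(result, data)
    return result


def standard_errors(fitres: FitResult, data: PreparedData, step: float = 1e-5) -> np.ndarray:
    """Observed-information SEs: sqrt(diag(2 H^{-1})), H the Hessian of -2LL.

    H is obtained by central finite differences of the analytic gradient.
    Parameters whose information is not invertible get NaN.
    """
    spec = fitres.spec
    sub = subset_for_spec(spec, data)
    x = fitres.theta.values
    k = len(x)
    H = np.empty((k, k))
    for i in range(k):
        h = step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = fiml_neg2ll(spec, ParameterSet(spec, xp), sub, return_grad=True)
        _, gm = fiml_neg2ll(spec, ParameterSet(spec, xm), sub, return_grad=True)
        H[i] = (gp - gm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; standard errors unavailable")
        return np.full(k, np.nan)
    d = np.diag(cov)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.where(d > 0, d, np.nan))
    return se


def lrt(fit_full: FitResult, fit_restricted: FitResult) -> ComparisonResult:
    """Likelihood-ratio test of a restricted model nested in a full one."""
    if not fit_full.spec.nests(fit_restricted.spec):
        raise ContractError(
            f"{fit_restricted.spec.name} is not nested in {fit_full.spec.name}"
        )
    if (
        fit_full.data_fingerprint
        and fit_restricted.data_fingerprint
        and fit_full.data_fingerprint != fit_restricted.data_fingerprint
    ):
        raise ContractError("fits come from different data sets")
    df = fit_full.spec.n_free - fit_restricted.spec.n_free
    if df < 1:
        raise ContractError("restricted model fixes no additional parameters")
    delta = fit_restricted.neg2ll - fit_full.neg2ll
    if delta < -1e-6:
        warnings.warn(f"negative LRT statistic {delta:.3g}; check convergence")
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, df)) if delta > 0 else 1.0
    preferred = fit_restricted.spec.name if p > 0.05 else fit_full.spec.name
    return ComparisonResult(
        delta_neg2ll=float(delta), df=df, p_value=p, preferred=preferred,
        full_name=fit_full.spec.name, restricted_name=fit_restricted.spec.name,
    )


def _selection_candidates(fitres: FitResult) -> List[str]:
    """Free paths eligible for fixation: never e-paths or intercepts, and
    never a main effect while its moderation coefficient is still free."""
    names = fitres.spec.free_paths
    out = []
    for name in names:
        if name.startswith("mu"):
            continue
        if name[0] == "e" and len(name) == 3:
            continue
        mod = _MAIN_TO_MOD.get(name)
        if mod is not None and mod in names:
            continue  # moderation term survives -> main effect stays
        out.append(name)
    return out


def backward_select(
    spec_full: ModelSpec,
    data: PreparedData,
    alpha: float = 0.05,
    options: Optional[FitOptions] = None,
) -> Tuple[FitResult, List[Dict]]:
    """Iterative fixation of non-significant paths, guarded by LRTs.

    At each round the eligible free paths are tried in increasing
    |estimate|/SE order; the first fixation whose LRT p-value exceeds
    *alpha* is kept (refits warm-start at the parent solution).  Stops when
    every candidate fixation is rejected.  Returns the final fit and the
    trail of comparisons.
    """
    options = options or FitOptions()
    current = fit(spec_full, data, options)
    trail: List[Dict] = []
    while True:
        if current.se is None or np.all(np.isnan(current.se)):
            warnings.warn("no usable SEs; stopping selection")
            break
        zvals = current.z_values()
        candidates = sorted(_selection_candidates(current), key=lambda n: zvals[n])
        accepted = False
        for cand in candidates:
            restricted_spec = replace(
                current.spec.drop(cand), name=f"{current.spec.name}−{cand}"
            )
            warm = current.theta.as_dict()
            warm.pop(cand, None)
            ropts = replace(options, starts=max(1, options.starts // 3), start_values=warm)
            try:
                rfit = fit(restricted_spec, data, ropts)
            except EstimationError:
                continue
            comp = lrt(current, rfit)
            trail.append(
                {
                    "fixed": cand,
                    "from": current.spec.name,
                    "delta_neg2ll": comp.delta_neg2ll,
                    "df": comp.df,
                    "p_value": comp.p_value,
                    "accepted": comp.p_value > alpha,
                    "aic_full": current.aic,
                    "aic_restricted": rfit.aic,
                }
            )
            if comp.p_value > alpha:
                current = rfit
                accepted = True
                break
        if not accepted:
            break
    return current, trail


# ---------------------------------------------------------------------------
# derived summaries


def standardized_components(a, c, e) -> VarianceDecomposition:
    """Path-traced standardized variance shares from unstandardized loadings.

    ``a``, ``c``, ``e`` are scalars or sequences of path coefficients into
    one phenotype; shares are sums of squares over the total, e.g. the
    heritability is ``sum(a^2) / (sum(a^2) + sum(c^2) + sum(e^2))``.
    Invariant to global sign flips.
    """
    sa = float(np.sum(np.square(np.atleast_1d(np.asarray(a, dtype=float)))))
    sc = float(np.sum(np.square(np.atleast_1d(np.asarray(c, dtype=float)))))
    se_ = float(np.sum(np.square(np.atleast_1d(np.asarray(e, dtype=float)))))
    total = sa + sc + se_
    if total == 0:
        raise ContractError("all loadings zero: variance shares undefined")
    return VarianceDecomposition({"A": sa / total, "C": sc / total, "E": se_ / total})


def model_decomposition(
    spec: ModelSpec, theta: ParameterSet, phenotype: str, m: float = 0.0
) -> VarianceDecomposition:
    """A/C/E shares of one phenotype's total variance via the reduced form.

    For multivariate models the squared reduced-form loadings on all A
    (resp. C, E) factors are summed, i.e. full path tracing including
    indirect beta-mediated contributions, at moderator value *m*.
    """
    from .biometric import _reduced_form, _values_full

    vals = _values_full(spec, theta)
    marr = np.array([float(m)])
    _, Lam, _, _ = _reduced_form(spec, vals, marr, np.array([True]))
    p = len(spec.phenotypes)
    ri = spec.phenotypes.index(phenotype)
    row = Lam[0, ri]
    return standardized_components(row[:p], row[p : 2 * p], row[2 * p :])


def confounding_share(beta_unadjusted: float, beta_adjusted: float) -> float:
    """Percent of an unadjusted beta path explained by confounding controls."""
    if beta_unadjusted == 0:
        raise ContractError("unadjusted beta is zero; share undefined")
    return 100.0 * (beta_unadjusted - beta_adjusted) / beta_unadjusted


def moderation_profile(
    fitres: FitResult,
    m_grid: Sequence[float],
    which: str = "beta32",
    x_grid: Optional[Sequence[float]] = None,
) -> Dict:
    """Moderated slope ``beta + gamma * m`` on a moderator grid.

    Also returns predicted-expectation lines versus the upstream phenotype
    at each m level (other predictors at 0), for prediction plots.  If the
    requested path is unmoderated the slope is constant, with a note.
    """
    if which not in ("beta32", "beta31"):
        raise ContractError("which must be 'beta32' or 'beta31'")
    gamma_name = _MAIN_TO_MOD[which]
    theta = fitres.theta
    beta = theta.get(which, 0.0)
    gamma = theta.get(gamma_name, 0.0)
    m_grid = np.asarray(m_grid, dtype=float)
    slopes = beta + gamma * m_grid
    note = None
    if gamma_name not in fitres.spec.free_paths:
        note = f"{which} is not moderated in {fitres.spec.name}; slope constant in m"
    x = np.asarray(x_grid if x_grid is not None else np.linspace(-3, 3, 61), dtype=float)
    lines = {}
    for mv, sl in zip(m_grid, slopes):
        intercept = theta.get("mu3", 0.0) + theta.get("b3", 0.0) * mv
        lines[float(mv)] = (x, intercept + sl * x)
    return {"m": m_grid, "slope": slopes, "note": note, "lines": lines, "which": which}
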