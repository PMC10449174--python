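"""Twin structural-equation models: specification, implied moments, FIML.

The model family is the (moderated) ACE-beta design for up to three
phenotypes ordered as cognitive ability (1), academic performance (2) and
educational expectations (3).  Each phenotype *i* loads on its own latent
additive-genetic (:math:`A_i`), shared-environment (:math:`C_i`) and
non-shared-environment (:math:`E_i`) factors, may receive cross-loadings
from upstream A/C factors, and is regressed on upstream phenotypes through
``beta`` paths.  All latent factors have unit variance; across co-twins the
A factors correlate 1 (MZ) or ``dz_genetic_correlation`` (DZ, default 0.5),
C factors correlate 1 and E factors 0.

A family-level moderator ``m`` (standardized parental education) enters the
means through ``b`` main effects and may moderate every path into the
expectations phenotype: a moderated coefficient is ``x + bx * m``, which
makes the implied covariance family-specific (a *definition variable*).

Structurally the system is recursive (triangular), so the reduced form is
obtained exactly by forward substitution: with direct-loading matrix ``D``
and strictly-lower beta matrix ``B``, the reduced-form loadings are
``Lambda = (I - B)^{-1} D`` and the implied within/cross-twin covariance
blocks are ``Lambda Lambda'`` and ``Lambda K Lambda'`` where ``K`` holds the
cross-twin latent correlations.

:func:`fiml_neg2ll` is the full-information ML objective: each pair
contributes -2 log of the multivariate-normal density of its *observed*
phenotype sub-vector under its own implied moments.  The analytic gradient
is returned alongside the value so that quasi-Newton fitting stays fast
even with per-family covariances.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PHENOTYPES",
    "ModelSpec",
    "ParameterSet",
    "ImpliedMoments",
    "ContractError",
    "spec_by_name",
    "parameter_universe",
    "implied_moments",
    "fiml_neg2ll",
    "twin_correlations",
    "select_family",
]

#: canonical phenotype order and 1-based indices used in parameter names
PHENOTYPES = ("iq", "grades", "exp")
_INDEX = {"iq": 1, "grades": 2, "exp": 3}

#: moderation coefficient -> the main-effect path it moderates
MODERATION_MAP = {
    "ba31": "a31",
    "bc31": "c31",
    "gamma31": "beta31",
    "ba32": "a32",
    "bc32": "c32",
    "gamma32": "beta32",
    "ba33": "a33",
    "bc33": "c33",
    "be33": "e33",
}
_MAIN_TO_MOD = {v: k for k, v in MODERATION_MAP.items()}

_PENALTY = 1e12


class ContractError(ValueError):
    """A caller violated an operation precondition."""


def parameter_universe(phenotypes: Sequence[str]) -> Tuple[str, ...]:
    """All parameter names admissible for a model on *phenotypes*.

    Names keep the canonical 1/2/3 indices of the full trivariate design even
    for sub-models, so e.g. a grades-only model uses ``a22, c22, e22, mu2``.
    """
    idx = [_INDEX[p] for p in phenotypes]
    if idx != sorted(idx):
        raise ValueError("phenotypes must respect the canonical order iq < grades < exp")
    names = []
    for i in idx:
        names += [f"a{i}{i}", f"c{i}{i}", f"e{i}{i}"]
    for i in idx:
        for k in idx:
            if k < i:
                names += [f"a{i}{k}", f"c{i}{k}", f"beta{i}{k}"]
    for i in idx:
        names += [f"b{i}", f"mu{i}"]
    if 3 in idx:
        for mod, main in MODERATION_MAP.items():
            if main in names:
                names.append(mod)
    return tuple(names)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of which paths are free, fixed to 0, or moderated.

    ``free_paths`` lists free parameters in canonical order; every other name
    in :func:`parameter_universe` is fixed to zero.  Moderation coefficients
    (``ba33``, ``gamma32``, ...) are themselves parameters: listing one frees
    the moderation of the corresponding main path.
    """

    name: str
    phenotypes: Tuple[str, ...]
    free_paths: Tuple[str, ...]
    family: str = "ACE"
    dz_genetic_correlation: float = 0.5

    def __post_init__(self):
        if self.family not in ("ACE", "ADE"):
            raise ValueError(f"family must be ACE or ADE, got {self.family!r}")
        if self.family == "ADE" and len(self.phenotypes) != 1:
            raise ValueError("ADE models are supported for univariate specs only")
        universe = parameter_universe(self.phenotypes)
        unknown = [p for p in self.free_paths if p not in universe]
        if unknown:
            raise ValueError(f"unknown parameters for {self.phenotypes}: {unknown}")
        for i in (_INDEX[p] for p in self.phenotypes):
            if f"e{i}{i}" not in self.free_paths:
                raise ValueError(f"e{i}{i} must be free (non-degenerate likelihood)")
        for mod, main in MODERATION_MAP.items():
            if mod in self.free_paths and main not in self.free_paths:
                raise ValueError(f"moderation {mod} requires its main effect {main} to be free")
        # canonical ordering
        ordered = tuple(p for p in universe if p in self.free_paths)
        object.__setattr__(self, "free_paths", ordered)

    @property
    def fixed_to_zero(self) -> Tuple[str, ...]:
        return tuple(p for p in parameter_universe(self.phenotypes) if p not in self.free_paths)

    @property
    def moderated_paths(self) -> Tuple[str, ...]:
        return tuple(MODERATION_MAP[p] for p in self.free_paths if p in MODERATION_MAP)

    @property
    def n_free(self) -> int:
        return len(self.free_paths)

    def drop(self, *names: str) -> "ModelSpec":
        """Spec with *names* (and any moderation of them) fixed to zero."""
        kill = set(names)
        for mod, main in MODERATION_MAP.items():
            if main in kill:
                kill.add(mod)
        return replace(
            self,
            name=f"{self.name}-{'-'.join(names)}",
            free_paths=tuple(p for p in self.free_paths if p not in kill),
        )

    def add(self, *names: str, name: Optional[str] = None) -> "ModelSpec":
        return replace(
            self,
            name=name or f"{self.name}+{'+'.join(names)}",
            free_paths=tuple(self.free_paths) + tuple(n for n in names if n not in self.free_paths),
        )

    def nests(self, other: "ModelSpec") -> bool:
        """True if *other* (restricted) is nested in self (full)."""
        return (
            self.phenotypes == other.phenotypes
            and self.family == other.family
            and set(other.free_paths) <= set(self.free_paths)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "phenotypes": list(self.phenotypes),
                "free_paths": list(self.free_paths),
                "family": self.family,
                "dz_genetic_correlation": self.dz_genetic_correlation,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            name=d["name"],
            phenotypes=tuple(d["phenotypes"]),
            free_paths=tuple(d["free_paths"]),
            family=d.get("family", "ACE"),
            dz_genetic_correlation=d.get("dz_genetic_correlation", 0.5),
        )


def _make_presets() -> Dict[str, ModelSpec]:
    tri = ("iq", "grades", "exp")
    m2a = (
        "a11", "c11", "e11", "a22", "c22", "e22", "a33", "e33",
        "beta32", "mu1", "mu2", "mu3",
    )
    m2b = m2a + ("a32", "c32")
    m2c = m2a + ("c32", "a21", "c21", "beta21", "a31", "c31", "beta31")
    m2d = m2a + ("a21", "beta21", "a31", "beta31", "b1", "b2", "b3")
    presets = {
        "M1a": ModelSpec("M1a", ("grades",), ("a22", "c22", "e22", "mu2")),
        "M1b": ModelSpec("M1b", ("exp",), ("a33", "c33", "e33", "mu3")),
        "M1c": ModelSpec("M1c", ("iq",), ("a11", "c11", "e11", "mu1")),
        "M2a": ModelSpec("M2a", tri, m2a),
        "M2b": ModelSpec("M2b", tri, m2b),
        "M2c": ModelSpec("M2c", tri, m2c),
        "M2d": ModelSpec("M2d", tri, m2d),
        "M3a": ModelSpec("M3a", tri, m2d + ("ba33", "gamma32")),
        "M3b": ModelSpec("M3b", tri, m2d + ("ba33", "gamma31")),
        # fully-moderated variants that backward selection starts from
        "M3a_full": ModelSpec(
            "M3a_full", tri,
            m2d + ("a32", "c32", "c33", "ba32", "bc32", "gamma32",
                   "ba33", "bc33", "be33"),
        ),
        "M3b_full": ModelSpec(
            "M3b_full", tri,
            m2d + ("a32", "c32", "c33", "c21", "c31",
                   "ba31", "bc31", "gamma31", "ba32", "bc32", "gamma32",
                   "ba33", "bc33", "be33"),
        ),
    }
    return presets


PRESETS = _make_presets()


def spec_by_name(name: str) -> ModelSpec:
    """Look up a named preset (M1a..M1c, M2a..M2d, M3a, M3b, *_full)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass
class ParameterSet:
    """Numeric values for the free parameters of a :class:`ModelSpec`.

    Values are stored in the spec's canonical free-parameter order.
    """

    spec: ModelSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_free,):
            raise ContractError(
                f"expected {self.spec.n_free} values for {self.spec.name}, "
                f"got shape {self.values.shape}"
            )

    @classmethod
    def from_dict(cls, spec: ModelSpec, mapping: Dict[str, float], strict: bool = True):
        unknown = set(mapping) - set(spec.free_paths)
        if strict and unknown:
            raise ContractError(f"values given for non-free parameters: {sorted(unknown)}")
        vals = np.array([mapping.get(p, 0.0) for p in spec.free_paths], dtype=float)
        return cls(spec, vals)

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.spec.free_paths.index(name)])
        except ValueError:
            raise KeyError(name) from None

    def get(self, name: str, default: float = 0.0) -> float:
        return self[name] if name in self.spec.free_paths else default

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.spec.free_paths, self.values.tolist()))

    def validate(self) -> None:
        for i in (_INDEX[p] for p in self.spec.phenotypes):
            if self[f"e{i}{i}"] <= 0:
                raise ContractError(f"e{i}{i} must be strictly positive")


@dataclass
class ImpliedMoments:
    """Model-implied mean vector and covariance of (twin1, twin2) phenotypes."""

    mean: np.ndarray  # (2p,)
    cov: np.ndarray  # (2p, 2p)
    zygosity: str
    m: float


# ---------------------------------------------------------------------------
# reduced-form construction


def _values_full(spec: ModelSpec, theta: "ParameterSet") -> Dict[str, float]:
    if theta.spec is not spec and theta.spec.free_paths != spec.free_paths:
        raise ContractError("ParameterSet does not conform to ModelSpec")
    vals = dict.fromkeys(parameter_universe(spec.phenotypes), 0.0)
    vals.update(theta.as_dict())
    return vals


def _reduced_form(spec: ModelSpec, vals: Dict[str, float], m: np.ndarray, zyg_is_mz: np.ndarray):
    """Return (T, Lambda, eta, wz): reduced-form transform, loadings (n,p,3p),
    means (n,p) and cross-twin latent weights (n,3p)."""
    idx = [_INDEX[p] for p in spec.phenotypes]
    p = len(idx)
    n = m.shape[0]

    def eff(name: str) -> np.ndarray:
        base = vals[name]
        mod = _MAIN_TO_MOD.get(name)
        if mod is not None and mod in vals and vals[mod] != 0.0:
            return base + vals[mod] * m
        return np.full(n, base)

    D = np.zeros((n, p, 3 * p))
    B = np.zeros((n, p, p))
    nu = np.zeros((n, p))
    for ri, i in enumerate(idx):
        D[:, ri, 2 * p + ri] = eff(f"e{i}{i}")
        for rk, k in enumerate(idx):
            if k > i:
                continue
            D[:, ri, rk] = eff(f"a{i}{k}")
            D[:, ri, p + rk] = eff(f"c{i}{k}")
            if k < i:
                B[:, ri, rk] = eff(f"beta{i}{k}")
        nu[:, ri] = vals[f"mu{i}"] + vals[f"b{i}"] * m
    # T = (I - B)^{-1} by forward substitution (B strictly lower triangular)
    T = np.tile(np.eye(p), (n, 1, 1))
    for ri in range(p):
        for rj in range(ri):
            acc = np.zeros(n)
            for rk in range(rj, ri):
                acc += B[:, ri, rk] * T[:, rk, rj]
            T[:, ri, rj] = acc
    Lam = np.einsum("nij,njk->nik", T, D)
    eta = np.einsum("nij,nj->ni", T, nu)
    # cross-twin latent correlations
    rho_a = np.where(zyg_is_mz, 1.0, spec.dz_genetic_correlation)
    if spec.family == "ADE":
        rho_c = np.where(zyg_is_mz, 1.0, 0.25)  # the "c" slot holds D loadings
    else:
        rho_c = np.ones(n)
    wz = np.zeros((n, 3 * p))
    wz[:, :p] = rho_a[:, None]
    wz[:, p : 2 * p] = rho_c[:, None]
    return T, Lam, eta, wz


def _sigma_blocks(Lam: np.ndarray, wz: np.ndarray):
    W = np.einsum("nic,njc->nij", Lam, Lam)
    Bc = np.einsum("nic,nc,njc->nij", Lam, wz, Lam)
    return W, Bc


def _assemble(W: np.ndarray, Bc: np.ndarray, eta: np.ndarray):
    n, p, _ = W.shape
    Sigma = np.empty((n, 2 * p, 2 * p))
    Sigma[:, :p, :p] = W
    Sigma[:, p:, p:] = W
    Sigma[:, :p, p:] = Bc
    Sigma[:, p:, :p] = np.swapaxes(Bc, 1, 2)
    mu = np.concatenate([eta, eta], axis=1)
    return Sigma, mu


def implied_moments(spec: ModelSpec, theta: ParameterSet, zygosity: str, m: float = 0.0) -> ImpliedMoments:
    """Exact model-implied mean and covariance for one family type.

    ``zygosity`` is ``"MZ"`` or ``"DZ"``; ``m`` the moderator value.
    """
    if zygosity not in ("MZ", "DZ"):
        raise ContractError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    vals = _values_full(spec, theta)
    marr = np.array([float(m)])
    _, Lam, eta, wz = _reduced_form(spec, vals, marr, np.array([zygosity == "MZ"]))
    W, Bc = _sigma_blocks(Lam, wz)
    Sigma, mu = _assemble(W, Bc, eta)
    return ImpliedMoments(mean=mu[0], cov=Sigma[0], zygosity=zygosity, m=float(m))


# ---------------------------------------------------------------------------
# FIML objective


def _data_columns(spec: ModelSpec) -> list:
    pos = [PHENOTYPES.index(p) for p in spec.phenotypes]
    return pos + [3 + q for q in pos]


def fiml_neg2ll(spec: ModelSpec, theta: ParameterSet, data, return_grad: bool = False):
    """Full-information ML -2 log-likelihood of *data* under (*spec*, *theta*).

    Each pair contributes the Gaussian density of its observed phenotype
    entries, marginalized by dropping the missing rows/columns of the
    pair-specific implied moments.  ``data`` needs arrays ``y`` (n, 6) with
    NaN for missing, ``m`` (n,) complete, ``zygosity`` (n,).  A pair with
    zero observed entries on the spec's phenotypes is a contract error.
    If any pair's marginal covariance is not positive definite a large
    penalty is returned.  With ``return_grad=True`` returns
    ``(value, gradient)`` where the gradient is analytic.
    """
    vals = _values_full(spec, theta)
    y = np.asarray(data.y, dtype=float)[:, _data_columns(spec)]
    m = np.asarray(data.m, dtype=float)
    zyg = np.asarray(data.zygosity)
    if np.any(np.isnan(m)):
        raise ContractError("moderator m contains missing values; drop those pairs upstream")
    n, d2 = y.shape
    p = d2 // 2
    obs = ~np.isnan(y)
    if np.any(~obs.any(axis=1)):
        bad = int(np.argmin(obs.any(axis=1)))
        raise ContractError(
            f"pair index {bad} has no observed phenotype for spec {spec.name}; "
            "it should have been dropped upstream"
        )
    zyg_is_mz = zyg == "MZ"
    T, Lam, eta, wz = _reduced_form(spec, vals, m, zyg_is_mz)
    W, Bc = _sigma_blocks(Lam, wz)
    Sigma, mu = _assemble(W, Bc, eta)
    resid = np.where(obs, y - mu, 0.0)

    # with every moderation coefficient at zero the covariance depends on
    # zygosity only, so groups can share one matrix factorization; the
    # grouping is data-determined, so cache it on the data object
    cache = getattr(data, "_fiml_groups", None)
    if cache is None or cache.get("shape") != y.shape:
        cache = {"shape": y.shape, "m_const": bool(len(np.unique(m)) == 1)}
        try:
            data._fiml_groups = cache
        except AttributeError:  # read-only container: recompute each call
            pass
    constant_cov = cache["m_const"] or all(
        vals.get(mod, 0.0) == 0.0 for mod in MODERATION_MAP
    )
    ckey = ("const", spec.phenotypes) if constant_cov else ("var", spec.phenotypes)
    if ckey not in cache:
        group_key = (
            obs if not constant_cov
            else np.column_stack([obs, zyg_is_mz[:, None]])
        )
        cache[ckey] = np.unique(group_key, axis=0, return_inverse=True)
    patterns, inverse = cache[ckey]
    nll = 0.0
    need_grad = return_grad
    if need_grad:
        P6 = np.zeros((n, d2, d2))
        v6 = np.zeros((n, d2))
    log2pi = math.log(2.0 * math.pi)
    for g, pat in enumerate(patterns):
        sel = np.nonzero(inverse == g)[0]
        o = np.nonzero(pat[:d2])[0]
        r = resid[np.ix_(sel, o)]
        if constant_cov:
            S1 = Sigma[sel[0]][np.ix_(o, o)]
            try:
                L1 = np.linalg.cholesky(S1)
            except np.linalg.LinAlgError:
                out = _PENALTY
                return (out, np.zeros(spec.n_free)) if return_grad else out
            logdet1 = 2.0 * float(np.sum(np.log(np.diag(L1))))
            P1 = np.linalg.inv(S1)
            v = r @ P1
            quad = np.einsum("ni,ni->n", r, v)
            nll += float(np.sum(len(o) * log2pi + logdet1 + quad))
            if need_grad:
                P6[np.ix_(sel, o, o)] = P1
                v6[np.ix_(sel, o)] = v
            continue
        So = Sigma[np.ix_(sel, o, o)]
        try:
            L = np.linalg.cholesky(So)
        except np.linalg.LinAlgError:
            out = _PENALTY
            return (out, np.zeros(spec.n_free)) if return_grad else out
        logdet = 2.0 * np.sum(np.log(np.einsum("nii->ni", L)), axis=1)
        v = np.linalg.solve(So, r[..., None])[..., 0]
        quad = np.einsum("ni,ni->n", r, v)
        nll += float(np.sum(len(o) * log2pi + logdet + quad))
        if need_grad:
            Po = np.linalg.inv(So)
            P6[np.ix_(sel, o, o)] = Po
            v6[np.ix_(sel, o)] = v
    if not return_grad:
        return nll

    # ---- analytic gradient --------------------------------------------
    # d(-2LL) = sum_n [ tr(P dSigma) - v' dSigma v - 2 v . dmu ]
    # expressed through a coefficient array Ctot on dLambda.
    P11 = P6[:, :p, :p]
    P22 = P6[:, p:, p:]
    P12 = P6[:, :p, p:]
    Q = P11 + P22
    R = P12 + np.swapaxes(P12, 1, 2)
    v1 = v6[:, :p]
    v2 = v6[:, p:]
    s1 = np.einsum("ni,nic->nc", v1, Lam)
    s2 = np.einsum("ni,nic->nc", v2, Lam)
    QL = np.einsum("nij,njc->nic", Q, Lam)
    RLw = np.einsum("nij,njc->nic", R, Lam) * wz[:, None, :]
    Ctot = 2.0 * (QL + RLw)
    Ctot -= 2.0 * (
        v1[:, :, None] * s1[:, None, :]
        + v2[:, :, None] * s2[:, None, :]
        + v1[:, :, None] * (wz * s2)[:, None, :]
        + v2[:, :, None] * (wz * s1)[:, None, :]
    )
    vsum = v1 + v2

    idx = [_INDEX[ph] for ph in spec.phenotypes]
    row_of = {i: ri for ri, i in enumerate(idx)}

    grad = np.zeros(spec.n_free)
    for k, name in enumerate(spec.free_paths):
        w = None  # None means weight 1
        base = name
        if name in MODERATION_MAP:
            base = MODERATION_MAP[name]
            w = m
        if base.startswith("beta"):
            i, kk = int(base[4]), int(base[5])
            ri, rk = row_of[i], row_of[kk]
            inner = np.einsum("nrc,nc->nr", Ctot, Lam[:, rk, :])
            gterm = np.einsum("nr,nr->n", T[:, :, ri], inner)
            mterm = np.einsum("nr,nr->n", vsum, T[:, :, ri]) * eta[:, rk]
            contrib = gterm - 2.0 * mterm
        elif base.startswith(("a", "c", "e")):
            i, kk = int(base[1]), int(base[2])
            ri, rk = row_of[i], row_of[kk]
            if base[0] == "a":
                col = rk
            elif base[0] == "c":
                col = p + rk
            else:
                col = 2 * p + rk
            contrib = np.einsum("nr,nr->n", T[:, :, ri], Ctot[:, :, col])
        elif base.startswith("mu") or base.startswith("b"):
            i = int(base[-1])
            ri = row_of[i]
            contrib = -2.0 * np.einsum("nr,nr->n", vsum, T[:, :, ri])
            if base.startswith("b"):
                w = m
        else:  # pragma: no cover
            raise AssertionError(name)
        grad[k] = float(np.sum(contrib if w is None else contrib * w))
    return nll, grad


# ---------------------------------------------------------------------------
# twin correlations and ACE/ADE family choice


def twin_correlations(data, min_pairs: int = 2) -> Dict[str, Dict[str, Optional[float]]]:
    """Double-entered Pearson twin correlations per phenotype and zygosity.

    Each complete pair contributes both orderings (y1, y2) and (y2, y1), so
    the statistic is invariant to twin labelling.  Pairs are used
    pairwise-complete per phenotype.  Returns
    ``{phenotype: {"rMZ": r, "rDZ": r}}`` with None (and a warning) where
    fewer than *min_pairs* complete pairs exist.
    """
    y = np.asarray(data.y, dtype=float)
    zyg = np.asarray(data.zygosity)
    out: Dict[str, Dict[str, Optional[float]]] = {}
    for q, pheno in enumerate(PHENOTYPES):
        out[pheno] = {}
        for zname in ("MZ", "DZ"):
            sel = zyg == zname
            a = y[sel, q]
            b = y[sel, 3 + q]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < min_pairs:
                warnings.warn(
                    f"fewer than {min_pairs} complete {zname} pairs for {pheno}; "
                    "correlation unavailable"
                )
                out[pheno][f"r{zname}"] = None
                continue
            x1 = np.concatenate([a[ok], b[ok]])
            x2 = np.concatenate([b[ok], a[ok]])
            out[pheno][f"r{zname}"] = float(stats.pearsonr(x1, x2)[0])
    return out


def select_family(corrs: Dict[str, Dict[str, Optional[float]]]) -> Dict[str, str]:
    """ADE if rDZ < rMZ / 2, otherwise ACE, per phenotype."""
    choice = {}
    for pheno, rr in corrs.items():
        rmz, rdz = rr.get("rMZ"), rr.get("rDZ")
        if rmz is None or rdz is None:
            raise ContractError(f"both twin correlations required for {pheno}")
        choice[pheno] = "ADE" if rdz < rmz / 2.0 else "ACE"
    return choice
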