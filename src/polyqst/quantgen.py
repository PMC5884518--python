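"""Plasticity index, REML variance components, and Q_ST / P_ST.

Two mixed models are fitted by REML:

* population model  y = Xb + Z_p u_p + e,  u_p ~ N(0, I s2_b),  e ~ N(0, I s2_w)
* animal model      y = Xb + Z_p u_p + Z_a u_a + e,
                    u_p ~ N(0, I s2_p),  u_a ~ N(0, 2G s2_a),  e ~ N(0, I s2_e)

with X the growth-chamber fixed factor (plus intercept) and 2G the
relationship matrix derived from marker-based kinship, floored to the
nearest positive semidefinite matrix by eigenvalue clipping.

The restricted likelihood is evaluated in the q-dimensional random-effect
space (Woodbury identity), so a fit costs O(q^3) per evaluation rather than
O(N^3); the optimizer is a log-parameterized quasi-Newton with three
deterministic restarts.

Q_ST is reported by default as s2_p / (s2_p + s2_a) — the convention this
package adopts for comparability with common-garden studies that omit the
factor two — with the textbook narrow-sense variant
s2_p / (s2_p + 2 s2_a) available everywhere via ``variant="textbook"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import minimize

from .data_io import TraitTable
from .popgen import KinshipMatrix

__all__ = [
    "PlasticityTable",
    "VarianceComponents",
    "QstEstimate",
    "plasticity_index",
    "fit_population_model",
    "fit_animal_model",
    "qst",
    "pst",
    "relationship_matrix",
    "NonConvergenceError",
]

BOUNDARY_REL_TOL = 1e-6


class NonConvergenceError(RuntimeError):
    """REML failed to converge from every deterministic restart."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class PlasticityTable:
    """Genotype x trait plasticity values in [0, 1] (NA if < 2 chambers)."""

    data: pd.DataFrame  # index individual_id, columns traits
    n_chambers: pd.DataFrame


def plasticity_index(traits: TraitTable, trait_names: list[str] | None = None) -> PlasticityTable:
    """(max - min) / max of each genotype's trait across growth chambers.

    The index summarizes the maximal plastic capacity of a genotype without
    regard to the direction of the response.  It is undefined (error) for
    negative trait values and NA (with a warning) where the maximum is zero
    or fewer than two chambers were observed.
    """
    names = list(trait_names or traits.trait_names)
    wide = traits.data
    rows = {}
    counts = {}
    for name in names:
        if (wide[name].dropna() < 0).any():
            raise ValueError(f"plasticity index undefined for negative values of {name!r}")
    for ind, sub in wide.groupby("individual_id", sort=False):
        vals = {}
        cnt = {}
        for name in names:
            v = sub[name].dropna().to_numpy()
            cnt[name] = len(v)
            if len(v) < 2:
                vals[name] = np.nan
            elif v.max() == 0:
                warnings.warn(f"trait {name!r} all-zero for {ind!r}: plasticity NA")
                vals[name] = np.nan
            else:
                vals[name] = (v.max() - v.min()) / v.max()
        rows[ind] = vals
        counts[ind] = cnt
    data = pd.DataFrame.from_dict(rows, orient="index")[names]
    data.index.name = "individual_id"
    n_chambers = pd.DataFrame.from_dict(counts, orient="index")[names]
    n_chambers.index.name = "individual_id"
    return PlasticityTable(data, n_chambers)


@dataclass
class VarianceComponents:
    """REML estimates with SEs, boundary flags and convergence diagnostics."""

    model: str  # "animal" | "population"
    components: dict[str, float]
    se: dict[str, float]
    boundary: dict[str, bool]
    non_identifiable: bool
    loglik: float
    converged: bool
    n_obs: int
    covariance: np.ndarray = field(default_factory=lambda: np.empty(0))
    names: tuple[str, ...] = ()


def _design_matrices(chamber, population, individual=None):
    """Fixed design (intercept + chamber dummies) and random incidence."""
    n = len(population)
    X = np.ones((n, 1))
    if chamber is not None:
        levels = list(pd.unique(pd.Series(chamber)))
        if len(levels) > 1:
            dummies = np.column_stack(
                [(np.asarray(chamber) == lev).astype(float) for lev in levels[1:]]
            )
            X = np.hstack([X, dummies])
    pops = list(pd.unique(pd.Series(population)))
    Zp = np.column_stack([(np.asarray(population) == p).astype(float) for p in pops])
    if individual is None:
        return X, Zp, None, None
    inds = list(pd.unique(pd.Series(individual)))
    Za = np.column_stack([(np.asarray(individual) == i).astype(float) for i in inds])
    return X, Zp, Za, inds


def relationship_matrix(G: KinshipMatrix, ids: list[str], clip_tol: float = 0.5) -> np.ndarray:
    """2G aligned to ``ids``, floored to PSD by eigenvalue clipping.

    Raises if the most negative eigenvalue exceeds ``clip_tol`` times the
    largest (the matrix is then too indefinite to trust the floor).
    """
    A = 2.0 * G.align(ids)
    A = 0.5 * (A + A.T)
    lam, Q = np.linalg.eigh(A)
    if lam[-1] <= 0:
        raise ValueError("relationship matrix has no positive eigenvalue")
    if -lam[0] > clip_tol * lam[-1]:
        raise ValueError(
            f"relationship matrix too indefinite (min eig {lam[0]:.3g} vs max "
            f"{lam[-1]:.3g}); check the kinship input"
        )
    return Q @ np.diag(np.clip(lam, 0.0, None)) @ Q.T


class _RemlProblem:
    """Restricted likelihood of y = Xb + sum_k B_k u_k + e in random-effect space.

    Each random part k contributes covariance s2_k B_k B_k'; the residual is
    s2_e I.  All cross-products are precomputed once; an evaluation is O(q^3).
    """

    def __init__(self, y, X, parts: list[tuple[str, np.ndarray]]):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.names = tuple(name for name, _ in parts) + ("residual",)
        self.B = np.hstack([B for _, B in parts])
        self.blocks = []
        start = 0
        for _, Bk in parts:
            self.blocks.append(slice(start, start + Bk.shape[1]))
            start += Bk.shape[1]
        self.N, self.p = self.X.shape
        self.q = self.B.shape[1]
        self.BtB = self.B.T @ self.B
        self.BtX = self.B.T @ self.X
        self.Bty = self.B.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def loglik(self, theta: np.ndarray) -> float:
        """REML log-likelihood (up to an additive constant)."""
        *sig, se = theta
        if se <= 0 or any(s < 0 for s in sig):
            return -np.inf
        g = np.empty(self.q)
        for s, blk in zip(sig, self.blocks):
            g[blk] = np.sqrt(max(s, 0.0))
        M = se * np.eye(self.q) + (g[:, None] * self.BtB) * g[None, :]
        try:
            L = scipy.linalg.cholesky(M, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError:
            return -np.inf
        logdet_V = (self.N - self.q) * np.log(se) + 2.0 * np.sum(np.log(np.diag(L)))
        rhs = np.column_stack([g[:, None] * self.BtX, g * self.Bty])
        sol = scipy.linalg.solve_triangular(L, rhs, lower=True, check_finite=False)
        sol_X, sol_y = sol[:, :-1], sol[:, -1]
        XtViX = (self.XtX - sol_X.T @ sol_X) / se
        XtViy = (self.Xty - sol_X.T @ sol_y) / se
        ytViy = (self.yty - sol_y @ sol_y) / se
        sign, logdet_XViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return -np.inf
        ytPy = ytViy - XtViy @ beta
        return -0.5 * (logdet_V + logdet_XViX + ytPy)


def _numerical_hessian(f, x, rel_step=1e-4):
    k = len(x)
    h = rel_step * np.maximum(np.abs(x), np.mean(np.abs(x)) + 1e-12)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _reml_optimize(problem: _RemlProblem, model: str) -> VarianceComponents:
    vy = float(np.var(problem.y)) or 1.0
    K = len(problem.names)
    floor = max(1e-10, 1e-10 * vy)
    # deterministic restarts: equal split, residual-heavy, genetic-heavy
    shares = [np.full(K, 1.0 / K)]
    resid_heavy = np.full(K, 0.1 / max(K - 1, 1))
    resid_heavy[-1] = 0.9
    shares.append(resid_heavy)
    gen_heavy = np.full(K, 0.9 / max(K - 1, 1))
    gen_heavy[-1] = 0.1
    shares.append(gen_heavy)

    def neg(phi):
        ll = problem.loglik(np.exp(phi))
        # large finite penalty keeps finite-difference gradients clean when a
        # probe point is numerically infeasible
        return -ll if np.isfinite(ll) else 1e12

    best = None
    trace = []
    for share in shares:
        phi0 = np.log(np.maximum(share * vy, floor))
        res = minimize(
            neg,
            phi0,
            method="L-BFGS-B",
            bounds=[(np.log(floor), np.log(vy * 1e4) + 1.0)] * K,
            options={"gtol": 1e-8, "ftol": 1e-12, "maxiter": 500},
        )
        trace.append((share.tolist(), float(res.fun), bool(res.success)))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-12):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise NonConvergenceError("REML optimizer failed from all restarts", trace)
    theta = np.exp(best.x)
    total = theta.sum()
    boundary = {n: bool(t < BOUNDARY_REL_TOL * total) for n, t in zip(problem.names, theta)}
    ll = problem.loglik(theta)

    # identifiability and SEs are judged on the components away from the zero
    # boundary: the observed information there must be well-conditioned
    H = _numerical_hessian(lambda t: -problem.loglik(np.abs(t)), theta)
    active = np.array([not boundary[n] for n in problem.names])
    non_identifiable = False
    cov = np.full((K, K), np.nan)
    if active.any():
        Ha = H[np.ix_(active, active)]
        diag = np.diag(Ha)
        try:
            if np.any(diag <= 0):
                non_identifiable = True
                cov_a = np.linalg.pinv(Ha)
            else:
                # correlation-normalized information: a (near-)zero eigenvalue
                # means a flat direction, i.e. confounded components
                d = 1.0 / np.sqrt(diag)
                C = Ha * np.outer(d, d)
                if np.linalg.eigvalsh(C).min() < 1e-4:
                    non_identifiable = True
                    cov_a = np.linalg.pinv(Ha)
                else:
                    cov_a = np.linalg.inv(Ha)
            cov[np.ix_(active, active)] = cov_a
        except np.linalg.LinAlgError:
            non_identifiable = True
    with np.errstate(invalid="ignore"):
        se = {n: float(np.sqrt(cov[i, i])) if cov[i, i] > 0 else np.nan
              for i, n in enumerate(problem.names)}
    return VarianceComponents(
        model=model,
        components={n: float(t) for n, t in zip(problem.names, theta)},
        se=se,
        boundary=boundary,
        non_identifiable=non_identifiable,
        loglik=float(ll),
        converged=bool(best.success),
        n_obs=problem.N,
        covariance=cov,
        names=problem.names,
    )


def _drop_missing(y, *factors):
    y = np.asarray(y, float)
    keep = ~np.isnan(y)
    out = [y[keep]]
    for f in factors:
        out.append(None if f is None else np.asarray(f, object)[keep])
    return out


def fit_population_model(y, chamber, population) -> VarianceComponents:
    """REML of the population mixed model: chamber fixed, population random.

    Returns components named ``sigma_b2`` (between-population) and
    ``sigma_w2`` (within-population residual).
    """
    y, chamber, population = _drop_missing(y, chamber, population)
    pops, counts = np.unique(population, return_counts=True)
    if len(pops) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("need >=2 populations with >=2 observations")
    X, Zp, _, _ = _design_matrices(chamber, population)
    problem = _RemlProblem(y, X, [("sigma_b2", Zp)])
    fit = _reml_optimize(problem, "population")
    fit.components["sigma_w2"] = fit.components.pop("residual")
    fit.se["sigma_w2"] = fit.se.pop("residual")
    fit.boundary["sigma_w2"] = fit.boundary.pop("residual")
    fit.names = ("sigma_b2", "sigma_w2")
    return fit


def fit_animal_model(y, chamber, population, individual, G: KinshipMatrix) -> VarianceComponents:
    """REML of the marker-kinship animal model.

    Random effects: population ~ N(0, I s2_p) and additive genetic values
    ~ N(0, 2G s2_a) with 2G the PSD-clipped relationship from Loiselle
    kinship; chamber enters as an unordered fixed factor (pass ``None`` for
    single-record plasticity models).  Components are named ``sigma_p2``,
    ``sigma_a2``, ``sigma_e2``.
    """
    y, chamber, population, individual = _drop_missing(y, chamber, population, individual)
    X, Zp, Za, ind_levels = _design_matrices(chamber, population, individual)
    A = relationship_matrix(G, ind_levels)
    lam, Q = np.linalg.eigh(A)
    La = Q * np.sqrt(np.clip(lam, 0.0, None))
    problem = _RemlProblem(y, X, [("sigma_p2", Zp), ("sigma_a2", Za @ La)])
    fit = _reml_optimize(problem, "animal")
    fit.components["sigma_e2"] = fit.components.pop("residual")
    fit.se["sigma_e2"] = fit.se.pop("residual")
    fit.boundary["sigma_e2"] = fit.boundary.pop("residual")
    fit.names = ("sigma_p2", "sigma_a2", "sigma_e2")
    return fit


@dataclass
class QstEstimate:
    """A Q_ST or P_ST value with its delta-method SE (NA when undefined)."""

    index: str  # "Q_ST" | "P_ST"
    value: float
    se: float
    variant: str
    trait: str | None = None
    c: float | None = None
    h2: float | None = None
    na_reason: str | None = None

    @property
    def is_na(self) -> bool:
        return self.na_reason is not None


def _ratio_delta_se(num, den_extra, weight, cov2):
    """SE of f = num / (num + weight*den_extra) by first-order delta method;
    cov2 is the 2x2 covariance of (num, den_extra)."""
    denom = num + weight * den_extra
    if denom <= 0 or cov2 is None or not np.all(np.isfinite(cov2)):
        return np.nan
    grad = np.array([weight * den_extra, -weight * num]) / denom**2
    var = float(grad @ cov2 @ grad)
    return float(np.sqrt(var)) if var > 0 else np.nan


def qst(v: VarianceComponents, variant: str = "printed", trait: str | None = None) -> QstEstimate:
    """Q_ST from animal-model components.

    ``printed`` (default): s2_p / (s2_p + s2_a); ``textbook``:
    s2_p / (s2_p + 2 s2_a).  NA when the components are jointly
    non-identifiable or jointly fixed at the zero boundary.
    """
    if v.model != "animal":
        raise ValueError("qst needs animal-model components")
    if variant not in ("printed", "textbook"):
        raise ValueError(f"unknown Q_ST variant {variant!r}")
    sp, sa = v.components["sigma_p2"], v.components["sigma_a2"]
    if v.non_identifiable:
        return QstEstimate("Q_ST", np.nan, np.nan, variant, trait, na_reason="non-identifiable")
    if v.boundary["sigma_p2"] and v.boundary["sigma_a2"]:
        return QstEstimate("Q_ST", np.nan, np.nan, variant, trait, na_reason="boundary")
    w = 1.0 if variant == "printed" else 2.0
    value = sp / (sp + w * sa)
    cov2 = v.covariance[:2, :2] if v.covariance.size else None
    se = _ratio_delta_se(sp, sa, w, cov2)
    return QstEstimate("Q_ST", float(value), se, variant, trait)


def pst(
    v: VarianceComponents,
    c: float = 1.0,
    h2: float = 1.0,
    variant: str = "brommer",
    trait: str | None = None,
) -> QstEstimate:
    """P_ST from population-model components.

    ``brommer`` (default): c*s2_b / (c*s2_b + 2*h2*s2_w) — heritability in
    the denominator, the form consistent with treating P_ST as a lower
    bound of Q_ST under c = h2 = 1; ``printed``:
    c*h2*s2_b / (c*h2*s2_b + s2_w).
    """
    if v.model != "population":
        raise ValueError("pst needs population-model components")
    if not (0 < c <= 1) or not (0 < h2 <= 1):
        raise ValueError("c and h2 must lie in (0, 1]")
    if variant not in ("brommer", "printed"):
        raise ValueError(f"unknown P_ST variant {variant!r}")
    sb, sw = v.components["sigma_b2"], v.components["sigma_w2"]
    if v.non_identifiable:
        return QstEstimate("P_ST", np.nan, np.nan, variant, trait, c, h2, "non-identifiable")
    if v.boundary["sigma_b2"] and v.boundary["sigma_w2"]:
        return QstEstimate("P_ST", np.nan, np.nan, variant, trait, c, h2, "boundary")
    cov2 = v.covariance[:2, :2] if v.covariance.size else None
    if variant == "brommer":
        value = c * sb / (c * sb + 2 * h2 * sw)
        se = np.nan
        denom = c * sb + 2 * h2 * sw
        if denom > 0 and cov2 is not None and np.all(np.isfinite(cov2)):
            grad = np.array([c * 2 * h2 * sw, -2 * h2 * c * sb]) / denom**2
            var = float(grad @ cov2 @ grad)
            se = float(np.sqrt(var)) if var > 0 else np.nan
    else:
        value = c * h2 * sb / (c * h2 * sb + sw)
        denom = c * h2 * sb + sw
        se = np.nan
        if denom > 0 and cov2 is not None and np.all(np.isfinite(cov2)):
            grad = np.array([c * h2 * sw, -c * h2 * sb]) / denom**2
            var = float(grad @ cov2 @ grad)
            se = float(np.sqrt(var)) if var > 0 else np.nan
    return QstEstimate("P_ST", float(value), se, variant, trait, c, h2)
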