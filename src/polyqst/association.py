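"""Mantel tests, diversity-trait correlations, and the allele-trait MANOVA.

The MANOVA screens alleles by abundance (present in >= 7 populations, or
rarer but above 5% frequency somewhere, minus near-fixed alleles), then
forward-selects allele presence/absence predictors per locus by
Pillai-trace MANOVA, pools retained alleles, checks order robustness by
permuting the introduction order, and reports per-trait regression slopes
for the retained alleles.  Presence/absence (not dosage) is forced by
hexaploid ambiguity.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeTable
from .popgen import AlleleFrequencies, DiversityProfile, allele_frequencies

__all__ = [
    "MantelResult",
    "AlleleScreen",
    "ManovaResult",
    "mantel",
    "diversity_trait_correlation",
    "allele_filter",
    "ztransform",
    "pillai_trace_test",
    "manova_stepwise",
]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    partial: bool = False
    conditioning_id: str | None = None


def _offdiag(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(len(d), k=1)
    return d[iu]


def _check_square(d: pd.DataFrame, name: str) -> np.ndarray:
    a = d.to_numpy(float)
    if d.shape[0] != d.shape[1] or list(d.index) != list(d.columns):
        raise ValueError(f"{name}: must be square with identical row/column labels")
    if not np.allclose(a, a.T, equal_nan=True):
        raise ValueError(f"{name}: not symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError(f"{name}: non-zero diagonal")
    return a


def _residualize(v: np.ndarray, on: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(on), on])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int | str = 999,
    seed: int = 0,
    conditioning: pd.DataFrame | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """(Partial) Mantel correlation between two labeled distance matrices.

    r is the Pearson correlation of the upper-triangle vectors; with a
    conditioning matrix both vectors are first residualized on it (partial
    Mantel).  p is by permuting rows/columns of the first matrix, add-one
    smoothed; ``n_perm="exact"`` enumerates all label permutations (n <= 8).
    """
    a1 = _check_square(d1, "d1")
    a2 = _check_square(d2, "d2")
    if list(d1.index) != list(d2.index):
        raise ValueError("distance matrices must share labels and order")
    n = len(a1)
    cond_vec = None
    if conditioning is not None:
        a3 = _check_square(conditioning, "conditioning")
        if list(conditioning.index) != list(d1.index):
            raise ValueError("conditioning matrix labels mismatch")
        cond_vec = _offdiag(a3)

    def statistic(m1: np.ndarray) -> float:
        v1, v2 = _offdiag(m1), _offdiag(a2)
        if cond_vec is not None and np.ptp(cond_vec) > 0:
            v1 = _residualize(v1, cond_vec)
            v2 = _residualize(v2, cond_vec)
        if v1.std() == 0 or v2.std() == 0:
            return np.nan
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = statistic(a1)
    if n_perm == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        perms = list(itertools.permutations(range(n)))[1:]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(int(n_perm))]
    count = 0
    for perm in perms:
        idx = np.asarray(perm)
        r_perm = statistic(a1[np.ix_(idx, idx)])
        if alternative == "greater":
            hit = r_perm >= r_obs
        elif alternative == "two-sided":
            hit = abs(r_perm) >= abs(r_obs)
        else:
            hit = r_perm <= r_obs
        count += bool(hit)
    p = (1 + count) / (len(perms) + 1)
    return MantelResult(
        r_obs,
        float(p),
        len(perms),
        partial=conditioning is not None,
        conditioning_id=None if conditioning is None else "conditioning",
    )


def diversity_trait_correlation(
    div: DiversityProfile, means: pd.DataFrame, diversity_col: str = "v"
) -> pd.DataFrame:
    """Pearson correlation of population diversity vs population trait means.

    ``means`` is population x trait.  Two-sided p from the t transform with
    n - 2 degrees of freedom; zero-variance columns give NA with a warning.
    """
    d = div.summary.set_index("population_id")[diversity_col]
    common = [p for p in means.index if p in d.index]
    if len(common) < 3:
        raise ValueError("need >= 3 populations with both diversity and trait means")
    rows = []
    for trait in means.columns:
        x = d.loc[common].to_numpy(float)
        y = means.loc[common, trait].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            warnings.warn(f"zero-variance or insufficient data for {trait!r}; NA")
            rows.append((trait, np.nan, np.nan, int(ok.sum())))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((trait, float(r), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["trait", "r", "p", "n"])


@dataclass
class AlleleScreen:
    """Classification of every allele with the reason kept or dropped."""

    table: pd.DataFrame  # locus, allele, n_pops, max_freq, min_freq, kept, reason
    presence_min_pops: int
    freq_threshold: float
    fixation_threshold: float
    pruned: list = field(default_factory=list)

    def kept(self) -> list[tuple[str, int]]:
        sub = self.table[self.table["kept"]]
        return list(zip(sub["locus"], sub["allele"]))

    def design_matrix(self, g: GenotypeTable) -> pd.DataFrame:
        """Individual x retained-allele presence (0/1) matrix."""
        cols = {}
        for locus, allele in self.kept():
            cols[f"{locus}_{allele}"] = [
                np.nan if c is None else float(allele in c) for c in g.data[locus]
            ]
        return pd.DataFrame(cols, index=list(g.individuals))


def allele_filter(
    g: GenotypeTable,
    freqs: AlleleFrequencies | None = None,
    presence_min_pops: int = 7,
    freq_threshold: float = 0.05,
    fixation_threshold: float = 0.95,
) -> AlleleScreen:
    """Abundance screen for MANOVA predictors.

    Keep an allele if present in >= ``presence_min_pops`` populations, or if
    rarer but exceeding ``freq_threshold`` frequency in some population;
    then drop alleles carried by >= ``fixation_threshold`` of the
    individuals of every population (near-fixation: a presence/absence
    predictor everyone carries has no contrast).  Kept + dropped partition
    the allele set.
    """
    freqs = freqs or allele_frequencies(g)
    rows = []
    for locus in g.loci:
        sub = freqs.table[freqs.table["locus"] == locus]
        carrier = {}
        for pop, pop_sub in g.data.groupby("population_id", sort=False):
            cells = [c for c in pop_sub[locus] if c is not None]
            if cells:
                carrier[pop] = {
                    a: np.mean([a in c for c in cells])
                    for a in {x for c in cells for x in c}
                }
        for allele in sorted(sub["allele"].unique()):
            fa = sub[sub["allele"] == allele].set_index("population_id")["freq"]
            present = int((fa > 0).sum())
            # absent populations count as frequency zero
            per_pop = fa.reindex(
                [p for p in g.population_ids() if (p, locus) in freqs.n], fill_value=0.0
            )
            fmax, fmin = float(per_pop.max()), float(per_pop.min())
            carrier_min = min(c.get(allele, 0.0) for c in carrier.values())
            if carrier_min >= fixation_threshold:
                kept, reason = False, "near-fixation"
            elif present >= presence_min_pops:
                kept, reason = True, f"present in >= {presence_min_pops} populations"
            elif fmax > freq_threshold:
                kept, reason = True, f"frequency > {freq_threshold} in some population"
            else:
                kept, reason = False, "rare/private"
            rows.append((locus, allele, present, fmax, fmin, kept, reason))
    table = pd.DataFrame(
        rows, columns=["locus", "allele", "n_pops", "max_freq", "min_freq", "kept", "reason"]
    )
    assert len(table) == table[["locus", "allele"]].drop_duplicates().shape[0]
    return AlleleScreen(table, presence_min_pops, freq_threshold, fixation_threshold)


def ztransform(df: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (mean 0, sd 1, ddof=1)."""
    return (df - df.mean()) / df.std(ddof=1)


def _residual_sscp(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return R.T @ R


def pillai_trace_test(
    Y: np.ndarray, X_reduced: np.ndarray, x_new: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Pillai trace for adding ``x_new`` to a multivariate regression.

    Returns (pillai, F, df1, df2, p) using the standard F approximation with
    hypothesis df q = added columns, error df = n - rank(full design).
    """
    X_full = np.column_stack([X_reduced, x_new])
    E = _residual_sscp(Y, X_full)
    H = _residual_sscp(Y, X_reduced) - E
    p_dim = Y.shape[1]
    q = x_new.shape[1] if x_new.ndim == 2 else 1
    ve = Y.shape[0] - np.linalg.matrix_rank(X_full)
    V = float(np.trace(H @ np.linalg.pinv(H + E)))
    s = min(p_dim, q)
    m = (abs(p_dim - q) - 1) / 2.0
    nn = (ve - p_dim - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or s - V <= 0:
        return V, np.nan, df1, df2, np.nan
    F = (df2 / df1) * (V / (s - V))
    p = float(stats.f.sf(F, df1, df2))
    return V, float(F), df1, df2, p


@dataclass
class ManovaResult:
    """Stepwise MANOVA outcome: retained alleles, Pillai tests, slopes."""

    retained: list[str]
    per_locus: pd.DataFrame  # locus, allele, pillai, F, p_entry, entered
    joint: pd.DataFrame  # allele, pillai, F, p_sequential, p_worst_order
    slopes: pd.DataFrame | None
    screen: AlleleScreen
    alpha_enter: float


def _forward_select(Y: np.ndarray, cols: dict[str, np.ndarray], alpha: float):
    selected: list[str] = []
    records = []
    X = np.ones((len(Y), 1))
    remaining = dict(cols)
    while remaining:
        best_name, best = None, None
        for name, x in remaining.items():
            V, F, df1, df2, p = pillai_trace_test(Y, X, x[:, None])
            if np.isnan(p):
                continue
            if best is None or p < best[4]:
                best_name, best = name, (V, F, df1, df2, p)
        if best is None or best[4] >= alpha:
            for name, x in remaining.items():
                V, F, df1, df2, p = pillai_trace_test(Y, X, x[:, None])
                records.append((name, V, F, p, False))
            break
        records.append((best_name, best[0], best[1], best[4], True))
        selected.append(best_name)
        X = np.column_stack([X, remaining.pop(best_name)])
    return selected, records


def manova_stepwise(
    traits: pd.DataFrame,
    screen: AlleleScreen,
    g: GenotypeTable,
    alpha_enter: float = 0.05,
    n_order_perm: int = 5000,
    seed: int = 0,
) -> ManovaResult:
    """Forward Pillai-MANOVA selection of allele predictors, per locus then
    pooled, with introduction-order permutation for order robustness.

    ``traits``: genotype x trait matrix (z-scored internally).  For each
    allele retained in the pooled model, the worst-case sequential p over
    permuted introduction orders is reported; per-trait univariate
    regression slopes are returned when anything is retained.
    """
    design = screen.design_matrix(g)
    common = [i for i in traits.index if i in design.index]
    Yd = ztransform(traits.loc[common].astype(float)).to_numpy()
    D = design.loc[common]
    # observation-wise missing handling: drop rows with any missing cell
    ok = np.isfinite(Yd).all(axis=1) & np.isfinite(D.to_numpy()).all(axis=1)
    Yd = Yd[ok]
    D = D.loc[np.asarray(common)[ok]]
    if len(Yd) <= Yd.shape[1] + 1:
        raise ValueError("too few genotypes for the trait degrees of freedom")
    per_locus_records = []
    pooled: list[str] = []
    for locus in g.loci:
        cols = {
            c: D[c].to_numpy(float)
            for c in D.columns
            if c.startswith(f"{locus}_") and np.ptp(D[c].to_numpy(float)) > 0
        }
        if not cols:
            continue
        selected, records = _forward_select(Yd, cols, alpha_enter)
        for name, V, F, p, entered in records:
            per_locus_records.append((locus, name, V, F, p, entered))
        pooled.extend(selected)
    per_locus = pd.DataFrame(
        per_locus_records, columns=["locus", "allele", "pillai", "F", "p", "entered"]
    )
    # prune rank-deficient pooled design
    pruned = []
    keep: list[str] = []
    X = np.ones((len(Yd), 1))
    for name in pooled:
        cand = np.column_stack([X, D[name].to_numpy(float)])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            keep.append(name)
            X = cand
        else:
            pruned.append(name)
            warnings.warn(f"allele {name} pruned: collinear in pooled design")
    screen.pruned.extend(pruned)

    joint_rows = []
    if keep:
        k = len(keep)
        all_orders = math.factorial(k)
        if all_orders <= n_order_perm:
            orders = list(itertools.permutations(range(k)))
        else:
            rng = np.random.default_rng(seed)
            # the discovery order is always evaluated so the worst-case p
            # dominates the reported sequential p
            orders = [tuple(range(k))] + [
                tuple(rng.permutation(k)) for _ in range(n_order_perm - 1)
            ]
        worst = {name: 0.0 for name in keep}
        cols_arr = {name: D[name].to_numpy(float) for name in keep}
        for order in orders:
            Xcur = np.ones((len(Yd), 1))
            for pos in order:
                name = keep[pos]
                V, F, df1, df2, p = pillai_trace_test(Yd, Xcur, cols_arr[name][:, None])
                if not np.isnan(p):
                    worst[name] = max(worst[name], p)
                Xcur = np.column_stack([Xcur, cols_arr[name]])
        # sequential stats in the discovery order
        Xcur = np.ones((len(Yd), 1))
        for name in keep:
            V, F, df1, df2, p = pillai_trace_test(Yd, Xcur, cols_arr[name][:, None])
            joint_rows.append((name, V, F, p, worst[name]))
            Xcur = np.column_stack([Xcur, cols_arr[name]])
    joint = pd.DataFrame(
        joint_rows, columns=["allele", "pillai", "F", "p_sequential", "p_worst_order"]
    )
    slopes = None
    if keep:
        Xfull = np.column_stack([np.ones(len(Yd))] + [D[n].to_numpy(float) for n in keep])
        beta, *_ = np.linalg.lstsq(Xfull, Yd, rcond=None)
        slopes = pd.DataFrame(beta[1:], index=keep, columns=list(traits.columns))
    return ManovaResult(keep, per_locus, joint, slopes, screen, alpha_enter)
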