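"""Ordinations, co-inertia with permutation test, and climate ANOVA.

The two-table workflow: genotype x trait means (z-scored) are ordinated by
PCA; individual genetic distances (Bruvo by default) by principal
coordinates.  Co-inertia between the two retained score tables is
summarized by the RV coefficient with a row-permutation test, and the first
co-inertia axis is regressed on ordinal climate codes (temperature 1-3,
precipitation 1-4) with sequential sums of squares, plus a one-way locality
ANOVA with Tukey HSD letter groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data_io import SiteTable, TraitTable

__all__ = [
    "OrdinationScores",
    "CoinertiaResult",
    "ClimateAnova",
    "trait_mean_table",
    "ordinate",
    "coinertia",
    "axis_climate_anova",
    "tukey_letters",
]


def trait_mean_table(
    traits: TraitTable, standardize: bool = True, trait_names: list[str] | None = None
) -> pd.DataFrame:
    """Per-genotype trait means over available chambers, z-scored by default.

    Genotypes missing a whole trait are dropped (with a warning) so the
    ordination input is complete.
    """
    names = list(trait_names or traits.trait_names)
    means = traits.data.groupby("individual_id", sort=False)[names].mean()
    incomplete = means.index[means.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"{len(incomplete)} genotype(s) dropped from ordination for missing "
            f"trait means: {list(incomplete[:5])}"
        )
        means = means.dropna()
    if standardize:
        means = (means - means.mean()) / means.std(ddof=1)
    return means


@dataclass
class OrdinationScores:
    """Individual scores on retained axes, ordered by decreasing eigenvalue."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    source: str  # "traits" | "markers" | ...


def _pca(x: pd.DataFrame, n_axes: int) -> OrdinationScores:
    M = x.to_numpy(float)
    M = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    eig = s**2 / (len(M) - 1)
    pos = int(np.sum(eig > 1e-12 * eig.max())) if eig.size else 0
    if pos < n_axes:
        raise ValueError(f"only {pos} positive eigenvalues; cannot retain {n_axes} axes")
    scores = pd.DataFrame(
        (U * s)[:, :n_axes], index=x.index, columns=[f"axis{i+1}" for i in range(n_axes)]
    )
    return OrdinationScores(scores, eig[:n_axes], eig[:n_axes] / eig.sum(), "traits")


def _pcoa(d: pd.DataFrame, n_axes: int, source: str) -> OrdinationScores:
    ids = [str(i) for i in d.index]
    dm = _SkbioDM(d.to_numpy(float), ids=ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    neg_mass = float(-eig[eig < 0].sum())
    pos_mass = float(eig[eig > 0].sum())
    if pos_mass > 0 and neg_mass / (neg_mass + pos_mass) > 0.20:
        # Lingoes correction: add 2*|lambda_min| to squared off-diagonal distances
        warnings.warn(
            "negative-eigenvalue mass exceeds 20%; applying Lingoes correction"
        )
        c = float(-eig.min())
        d2 = d.to_numpy(float) ** 2 + 2 * c
        np.fill_diagonal(d2, 0.0)
        dm = _SkbioDM(np.sqrt(d2), ids=ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _skbio_pcoa(dm, method="eigh")
        eig = res.eigvals.to_numpy()
    pos = int(np.sum(eig > 1e-12 * max(eig.max(), 1e-300)))
    if pos < n_axes:
        raise ValueError(f"only {pos} positive eigenvalues; cannot retain {n_axes} axes")
    scores = pd.DataFrame(
        res.samples.to_numpy()[:, :n_axes],
        index=d.index,
        columns=[f"axis{i+1}" for i in range(n_axes)],
    )
    total = float(eig[eig > 0].sum())
    return OrdinationScores(scores, eig[:n_axes], eig[:n_axes] / total, source)


def ordinate(x: pd.DataFrame, n_axes: int = 2, source: str | None = None) -> OrdinationScores:
    """PCA of a (standardized) trait matrix, or PCoA of a distance matrix.

    A square DataFrame with identical index and columns and zero diagonal is
    treated as a distance matrix; anything else as a feature matrix.
    """
    is_dist = (
        x.shape[0] == x.shape[1]
        and list(x.index) == list(x.columns)
        and np.allclose(np.diag(x.to_numpy(float)), 0.0)
    )
    if is_dist:
        return _pcoa(x, n_axes, source or "markers")
    scores = _pca(x, n_axes)
    if source:
        scores.source = source
    return scores


@dataclass
class CoinertiaResult:
    """RV coefficient, permutation p, axis loadings and projections."""

    rv: float
    p_value: float
    n_perm: int
    singular_values: np.ndarray
    loadings_a: np.ndarray
    loadings_b: np.ndarray
    projections_a: pd.DataFrame
    projections_b: pd.DataFrame


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV = tr(XX'YY') / sqrt(tr((XX')^2) tr((YY')^2)) on column-centered X, Y."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    num = float(np.sum((X.T @ Y) ** 2))
    den = float(np.sqrt(np.sum((X.T @ X) ** 2) * np.sum((Y.T @ Y) ** 2)))
    return num / den if den > 0 else np.nan


def coinertia(
    a: OrdinationScores, b: OrdinationScores, n_perm: int = 999, seed: int = 0
) -> CoinertiaResult:
    """Co-inertia of two score tables over the same individuals.

    Strength is the RV coefficient; significance is by permuting the rows
    of the second table ``n_perm`` times with add-one smoothing.
    """
    if list(a.scores.index) != list(b.scores.index):
        raise ValueError("score tables must cover the same individuals in the same order")
    X = a.scores.to_numpy(float)
    Y = b.scores.to_numpy(float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
    rv_obs = rv_coefficient(X, Y)
    rng = np.random.default_rng(seed)
    n = len(X)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if rv_coefficient(X, Y[perm]) >= rv_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    k = len(s)
    cols = [f"coa{i+1}" for i in range(k)]
    proj_a = pd.DataFrame(Xc @ U, index=a.scores.index, columns=cols)
    proj_b = pd.DataFrame(Yc @ Vt.T, index=b.scores.index, columns=cols)
    return CoinertiaResult(float(rv_obs), float(p), n_perm, s, U, Vt.T, proj_a, proj_b)


@dataclass
class ClimateAnova:
    """Sequential climate ANOVA and one-way locality ANOVA on a COA axis."""

    environment: pd.DataFrame  # term, df, F, p, explained_pct
    locality: pd.DataFrame
    letters: dict[str, str]


def tukey_letters(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from Tukey HSD: groups sharing no letter differ."""
    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    names = list(res.groupsunique)
    sig_pairs = [
        (str(r[0]), str(r[1]))
        for r, rej in zip(res.summary().data[1:], res.reject)
        if rej
    ]
    # insert-and-absorb construction of the letter sets
    sets: list[set[str]] = [set(names)]
    for g1, g2 in sig_pairs:
        for st in list(sets):
            if g1 in st and g2 in st:
                sets.remove(st)
                for drop in (g1, g2):
                    cand = st - {drop}
                    if cand and not any(cand <= other for other in sets):
                        sets.append(cand)
        sets = [s for s in sets if not any(s < o for o in sets if o is not s)]
    sets.sort(key=lambda s: sorted(s))
    letters = {name: "" for name in names}
    for i, st in enumerate(sets):
        ch = chr(ord("a") + i)
        for name in sorted(st):
            letters[name] += ch
    return letters


def axis_climate_anova(
    scores: pd.Series, populations: pd.Series, sites: SiteTable, alpha: float = 0.05
) -> ClimateAnova:
    """Sequential-SS ANOVA of a COA axis on numeric climate codes.

    Temperature is coded 1-3 (ALP<SUB<BOR) and precipitation 1-4; their
    product enters as the interaction.  Explained variation is
    SS_term / SS_total * 100.  A separate one-way locality ANOVA provides
    Tukey HSD letter groups.
    """
    site = sites.data.set_index("population_id")
    tcode = sites.temperature_code()
    tmap = dict(zip(sites.data["population_id"], tcode))
    pmap = dict(zip(site.index, site["precipitation_class"].astype(int)))
    missing = set(populations) - set(tmap)
    if missing:
        raise ValueError(f"individuals mapped to unknown populations: {sorted(missing)}")
    df = pd.DataFrame(
        {
            "y": scores.to_numpy(float),
            "temperature": [tmap[p] for p in populations],
            "precipitation": [pmap[p] for p in populations],
            "locality": list(populations),
        },
        index=scores.index,
    )
    if np.isclose(df["y"].var(ddof=0), 0.0):
        raise ValueError("constant response: F undefined")
    model = smf.ols("y ~ temperature + precipitation + temperature:precipitation", df).fit()
    tab = sm.stats.anova_lm(model, typ=1)
    ss_total = float(tab["sum_sq"].sum())
    env = pd.DataFrame(
        {
            "term": tab.index,
            "df": tab["df"].astype(int).to_numpy(),
            "F": tab["F"].to_numpy(),
            "p": tab["PR(>F)"].to_numpy(),
            "explained_pct": 100.0 * tab["sum_sq"].to_numpy() / ss_total,
        }
    )
    loc_model = smf.ols("y ~ C(locality)", df).fit()
    loc_tab = sm.stats.anova_lm(loc_model, typ=1)
    loc_total = float(loc_tab["sum_sq"].sum())
    locality = pd.DataFrame(
        {
            "term": loc_tab.index,
            "df": loc_tab["df"].astype(int).to_numpy(),
            "F": loc_tab["F"].to_numpy(),
            "p": loc_tab["PR(>F)"].to_numpy(),
            "explained_pct": 100.0 * loc_tab["sum_sq"].to_numpy() / loc_total,
        }
    )
    letters = tukey_letters(df["y"].to_numpy(), df["locality"].to_numpy(), alpha)
    return ClimateAnova(env, locality, letters)
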