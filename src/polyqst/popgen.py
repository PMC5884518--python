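"""Marker statistics for hexaploid codominant data.

Allele dosage is unobservable from fragment sizes in a hexaploid, so all
estimators here work on *allelic phenotypes*: the set of distinct allele
lengths recorded per individual.  The default frequency estimator counts
each distinct allele once per individual; within-individual frequencies are
presence / set-size.  Both conventions are pluggable where it matters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .data_io import GenotypeTable

__all__ = [
    "AlleleFrequencies",
    "DifferentiationResult",
    "KinshipMatrix",
    "DiversityProfile",
    "allele_frequencies",
    "fst_global",
    "rst_global",
    "loiselle_kinship",
    "bruvo_distances",
    "bruvo_set_distance",
    "diversity_profile",
]


@dataclass
class AlleleFrequencies:
    """Per population x locus allele counts and simplex-normalized frequencies.

    ``table`` is long format: population_id, locus, allele, count, freq.
    ``n`` maps (population_id, locus) -> total allele observations.
    """

    table: pd.DataFrame
    n: dict[tuple[str, str], int]
    estimator: str = "allelic_phenotype"

    def freqs(self, population: str, locus: str) -> pd.Series:
        sub = self.table[
            (self.table["population_id"] == population) & (self.table["locus"] == locus)
        ]
        return pd.Series(sub["freq"].values, index=sub["allele"].values)

    def pooled(self, locus: str) -> pd.Series:
        """Whole-sample frequencies at a locus (counts pooled over populations)."""
        sub = self.table[self.table["locus"] == locus]
        counts = sub.groupby("allele")["count"].sum()
        return counts / counts.sum()

    def population_presence(self, locus: str, allele: int) -> int:
        sub = self.table[
            (self.table["locus"] == locus)
            & (self.table["allele"] == allele)
            & (self.table["count"] > 0)
        ]
        return sub["population_id"].nunique()


@dataclass
class DifferentiationResult:
    """A differentiation index with jackknife SE and per-locus values."""

    index: str  # "F_ST" | "R_ST" | ...
    value: float
    se: float
    per_locus: pd.Series
    undefined: bool = False
    extras: dict = field(default_factory=dict)


@dataclass
class KinshipMatrix:
    """Symmetric Loiselle-type kinship over individuals.

    The diagonal holds the estimator's self-kinship and is carried along but
    plays no pairwise role; the animal model derives its relationship matrix
    as 2*values with documented PSD clipping.
    """

    values: np.ndarray
    individual_ids: list[str]
    reference: str = "sample-mean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids, columns=self.individual_ids)

    def align(self, ids: list[str]) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"individuals absent from kinship matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


def allele_frequencies(g: GenotypeTable, estimator: str = "allelic_phenotype") -> AlleleFrequencies:
    """Estimate allele frequencies per population x locus.

    Default counts each distinct allele observed in an individual once
    (allelic-phenotype counting); exact dosages being unobservable, this
    overestimates rare and underestimates abundant allele frequencies — a
    known, accepted bias of polyploid microsatellite data.
    """
    if estimator != "allelic_phenotype":
        raise ValueError(f"unknown frequency estimator {estimator!r}")
    rows = []
    n: dict[tuple[str, str], int] = {}
    for locus in g.loci:
        for pop, sub in g.data.groupby("population_id", sort=False):
            counts: dict[int, int] = {}
            total = 0
            for cell in sub[locus]:
                if cell is None:
                    continue
                for a in cell:
                    counts[a] = counts.get(a, 0) + 1
                    total += 1
            if total == 0:
                warnings.warn(
                    f"population {pop!r} has no data at locus {locus!r}; locus "
                    "dropped for that population"
                )
                continue
            n[(pop, locus)] = total
            for a, c in sorted(counts.items()):
                rows.append((pop, locus, a, c, c / total))
    table = pd.DataFrame(rows, columns=["population_id", "locus", "allele", "count", "freq"])
    return AlleleFrequencies(table, n, estimator)


def _anova_components(values_by_pop: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA variance components (sigma_among, sigma_within) with the
    unequal-n coefficient n_c; returns (0-able) method-of-moments estimates
    without truncation so that ratio-of-sums aggregation stays unbiased."""
    groups = [v for v in values_by_pop if len(v) > 0]
    r = len(groups)
    ns = np.array([len(v) for v in groups], dtype=float)
    ntot = ns.sum()
    if r < 2 or ntot <= r:
        return np.nan, np.nan
    means = np.array([v.mean() for v in groups])
    grand = np.concatenate(groups).mean()
    msa = float(np.sum(ns * (means - grand) ** 2) / (r - 1))
    ssw = float(sum(((v - m) ** 2).sum() for v, m in zip(groups, means)))
    msw = ssw / (ntot - r)
    nc = (ntot - np.sum(ns**2) / ntot) / (r - 1)
    sigma_a = (msa - msw) / nc
    return sigma_a, msw


def _locus_observations(g: GenotypeTable, locus: str) -> dict[str, list[tuple[int, ...]]]:
    obs: dict[str, list[tuple[int, ...]]] = {}
    for pop, sub in g.data.groupby("population_id", sort=False):
        cells = [c for c in sub[locus] if c is not None]
        if cells:
            obs[pop] = cells
    return obs


def _ratio_of_sums_jackknife(num: np.ndarray, den: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Multilocus ratio-of-sums with delete-one-locus jackknife SE."""
    ok = ~np.isnan(num)
    num, den = num[ok], den[ok]
    total = num.sum() / den.sum()
    L = len(num)
    if L < 2:
        return total, np.nan, num / den
    loo = np.array([(num.sum() - num[l]) / (den.sum() - den[l]) for l in range(L)])
    se = float(np.sqrt((L - 1) / L * np.sum((loo - loo.mean()) ** 2)))
    return total, se, num / den


def fst_global(g: GenotypeTable) -> DifferentiationResult:
    """ANOVA-based multilocus F_ST on allelic-phenotype indicator variables.

    The decomposition is nested: per locus and allele, the among-population
    component is estimated by one-way ANOVA of the within-individual allele
    frequencies p_ia = presence/|set| (individuals, not single allele
    observations, are the exchangeable unit — this keeps the component
    estimators unbiased under dosage masking), while the within-population
    total — the between-individual plus within-individual indicator
    variance — reduces to the heterozygosity mu(1-mu) of the expected
    within-individual frequency, estimated without bias per population as
    mhat - mhat^2 + s^2/n.  F_ST = sum among / sum (among + within), the
    multilocus value is the ratio of summed components, and the SE is a
    delete-one-locus jackknife.
    """
    nums, dens = [], []
    pops_order = list(pd.unique(g.data["population_id"]))
    for locus in g.loci:
        P, alleles = _individual_frequency_matrix(g, locus)
        pop_arr = g.data["population_id"].to_numpy()
        present = ~np.isnan(P[:, 0]) if len(alleles) else np.zeros(len(P), bool)
        a_sum = w_sum = 0.0
        ok = len(alleles) > 1
        for j in range(len(alleles)):
            groups = [
                P[(pop_arr == p) & present, j] for p in pops_order
            ]
            groups = [v for v in groups if len(v)]
            sa, _ = _anova_components(groups)
            if np.isnan(sa):
                ok = False
                break
            # unbiased per-population estimate of mu(1-mu), averaged
            w_terms = []
            for v in groups:
                m = v.mean()
                s2 = v.var(ddof=1) if len(v) > 1 else 0.0
                w_terms.append(m - m * m + s2 / len(v))
            a_sum += sa
            w_sum += float(np.mean(w_terms))
        if not ok or (a_sum + w_sum) <= 0:
            nums.append(np.nan)
            dens.append(np.nan)
        else:
            nums.append(a_sum)
            dens.append(a_sum + w_sum)
    nums, dens = np.array(nums, float), np.array(dens, float)
    if np.all(np.isnan(nums)) or np.nansum(dens) == 0:
        return DifferentiationResult("F_ST", np.nan, np.nan, pd.Series(dtype=float), undefined=True)
    value, se, per_locus = _ratio_of_sums_jackknife(nums, dens)
    loci = [l for l, v in zip(g.loci, nums) if not np.isnan(v)]
    return DifferentiationResult("F_ST", float(value), se, pd.Series(per_locus, index=loci))


def rst_global(g: GenotypeTable) -> DifferentiationResult:
    """Slatkin-style multilocus R_ST from ANOVA of allele sizes in repeat units."""
    nums, dens = [], []
    for locus in g.loci:
        rep = g.repeat_lengths[locus]
        obs = _locus_observations(g, locus)
        groups = [
            np.array([a / rep for c in cells for a in c], dtype=float)
            for cells in obs.values()
        ]
        sa, sw = _anova_components(groups)
        if np.isnan(sa) or (sa + sw) == 0:
            nums.append(np.nan)
            dens.append(np.nan)
        else:
            nums.append(sa)
            dens.append(sa + sw)
    nums, dens = np.array(nums, float), np.array(dens, float)
    if np.all(np.isnan(nums)):
        return DifferentiationResult("R_ST", np.nan, np.nan, pd.Series(dtype=float), undefined=True)
    value, se, per_locus = _ratio_of_sums_jackknife(nums, dens)
    loci = [l for l, v in zip(g.loci, nums) if not np.isnan(v)]
    return DifferentiationResult("R_ST", float(value), se, pd.Series(per_locus, index=loci))


def _individual_frequency_matrix(
    g: GenotypeTable, locus: str
) -> tuple[np.ndarray, list[int]]:
    """N x A matrix of within-individual allele frequencies (presence/|set|);
    rows of NaN where the individual is missing at the locus."""
    alleles = sorted({a for c in g.data[locus] if c is not None for a in c})
    pos = {a: j for j, a in enumerate(alleles)}
    P = np.full((len(g.data), len(alleles)), np.nan)
    for i, cell in enumerate(g.data[locus]):
        if cell is None:
            continue
        P[i] = 0.0
        for a in cell:
            P[i, pos[a]] = 1.0 / len(cell)
    return P, alleles


def loiselle_kinship(
    g: GenotypeTable,
    reference: AlleleFrequencies | None = None,
    correction: str = "empirical",
) -> KinshipMatrix:
    """Frequency-centered pairwise kinship for dosage-masked polyploid data.

    F_ij = sum_l sum_a [(p_ila - pbar_la)(p_jla - pbar_la) + corr_la]
           / sum_l sum_a pbar_la (1 - pbar_la)

    with p_ila the within-individual allele frequency.  The default centers
    on the sample mean of individual frequencies and uses the small-sample
    correction corr_la = Var(p_.la)/(N_l - 1) (the empirical analogue, for
    frequency-valued observations, of the gene-copy term pbar(1-pbar)/(n-1));
    this makes the mean over all ordered pairs exactly zero when the
    reference is the sample itself.  ``correction="loiselle"`` applies the
    literal gene-copy term instead; an explicit ``reference`` recenters on
    pooled whole-sample count frequencies (e.g. for cross-dataset use).
    """
    if correction not in ("empirical", "loiselle"):
        raise ValueError(f"unknown correction {correction!r}")
    N = len(g.data)
    num = np.zeros((N, N))
    den = np.zeros((N, N))
    any_data = np.zeros(N, dtype=bool)
    for locus in g.loci:
        P, alleles = _individual_frequency_matrix(g, locus)
        present = ~np.isnan(P[:, 0])
        n_ind = int(present.sum())
        if n_ind < 2:
            continue
        any_data |= present
        if reference is not None:
            pooled = reference.pooled(locus)
            pbar = np.array([pooled.get(a, 0.0) for a in alleles])
        else:
            pbar = np.nanmean(P, axis=0)
        C = P - pbar  # NaN rows propagate
        if correction == "empirical":
            var = np.nanmean((P - np.nanmean(P, axis=0)) ** 2, axis=0)
            corr = float(var.sum() / (n_ind - 1))
        else:
            n_obs = int(sum(len(c) for c in g.data[locus] if c is not None))
            corr = float(np.sum(pbar * (1 - pbar)) / (n_obs - 1))
        cross = np.where(present, 1.0, np.nan)[:, None] * np.where(present, 1.0, np.nan)[None, :]
        num_l = (np.nan_to_num(C) @ np.nan_to_num(C).T + corr) * cross
        den_l = float(np.sum(pbar * (1 - pbar))) * cross
        num += np.nan_to_num(num_l)
        den += np.nan_to_num(den_l)
    if not any_data.all():
        dropped = [i for i, ok in zip(g.individuals, any_data) if not ok]
        warnings.warn(f"individuals with no data at any locus excluded: {dropped}")
    keep = np.where(any_data)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        F = num[np.ix_(keep, keep)] / den[np.ix_(keep, keep)]
    ids = [g.individuals.iloc[i] for i in keep]
    provenance = "sample-mean" if reference is None else "external-pooled"
    return KinshipMatrix(F, ids, provenance)


def bruvo_allele_distance(x: float, y: float, repeat: float) -> float:
    """1 - 2^(-|x-y|/repeat): microsatellite allele distance in [0, 1)."""
    return 1.0 - 2.0 ** (-abs(x - y) / repeat)


def bruvo_set_distance(a: tuple[int, ...], b: tuple[int, ...], repeat: float) -> float:
    """Bruvo distance between two dosage-masked allele sets at one locus.

    Genome-addition convention: the smaller set is padded to the larger
    size with copies of its own alleles, exhaustively over fill-ins (sets
    have at most 6 distinct alleles); each padded pair is scored by the
    minimum-weight perfect matching; the minimum over fill-ins is returned.
    """
    if len(a) > len(b):
        a, b = b, a
    k = len(b)
    best = np.inf
    for fill in itertools.combinations_with_replacement(a, k - len(a)):
        padded = list(a) + list(fill)
        D = np.array([[bruvo_allele_distance(x, y, repeat) for y in b] for x in padded])
        ri, ci = linear_sum_assignment(D)
        best = min(best, float(D[ri, ci].sum()) / k)
    return best


def bruvo_distances(g: GenotypeTable) -> pd.DataFrame:
    """Individual x individual Bruvo distance matrix (mean over shared loci)."""
    N = len(g.data)
    total = np.zeros((N, N))
    shared = np.zeros((N, N))
    for locus in g.loci:
        rep = g.repeat_lengths[locus]
        cells = list(g.data[locus])
        uniq = sorted({c for c in cells if c is not None})
        cache: dict[tuple, float] = {}
        for ca, cb in itertools.combinations_with_replacement(uniq, 2):
            cache[(ca, cb)] = cache[(cb, ca)] = bruvo_set_distance(ca, cb, rep)
        for i, j in itertools.combinations(range(N), 2):
            if cells[i] is None or cells[j] is None:
                continue
            d = cache[(cells[i], cells[j])]
            total[i, j] += d
            total[j, i] += d
            shared[i, j] += 1
            shared[j, i] += 1
        for i in range(N):
            if cells[i] is not None:
                shared[i, i] += 1
    with np.errstate(invalid="ignore"):
        D = np.where(shared > 0, total / np.maximum(shared, 1), np.nan)
    np.fill_diagonal(D, 0.0)
    ids = list(g.individuals)
    return pd.DataFrame(D, index=ids, columns=ids)


def _rarefied_richness(counts: np.ndarray, g_sub: int) -> float:
    """Expected allele count in a hypergeometric subsample of size g_sub."""
    n = counts.sum()
    # 1 - C(n - c, g)/C(n, g) per allele, in log space for stability
    out = 0.0
    for c in counts:
        if n - c < g_sub:
            out += 1.0
        else:
            log_p = (
                gammaln(n - c + 1)
                - gammaln(g_sub + 1)
                - gammaln(n - c - g_sub + 1)
                - (gammaln(n + 1) - gammaln(g_sub + 1) - gammaln(n - g_sub + 1))
            )
            out += 1.0 - np.exp(log_p)
    return float(out)


@dataclass
class DiversityProfile:
    """Per-population diversity indices, per locus and multilocus means.

    ``per_locus``: population_id, locus, n, A, Ae, Ar, He, v.
    ``summary``: multilocus (unweighted across loci) means per population.
    For non-ordered alleles the Pons-Petit within-population diversity
    estimator coincides with unbiased gene diversity n/(n-1)(1 - sum p^2);
    ``v`` is that estimator averaged the Pons-Petit way (plain mean over
    loci), kept as a separate column for clarity of provenance.
    """

    per_locus: pd.DataFrame
    summary: pd.DataFrame
    rarefaction_g: int


def diversity_profile(g: GenotypeTable, rarefaction_g: int) -> DiversityProfile:
    if rarefaction_g < 2:
        raise ValueError("rarefaction size must be >= 2")
    freqs = allele_frequencies(g)
    min_n = min(freqs.n.values())
    if rarefaction_g > min_n:
        raise ValueError(
            f"rarefaction size {rarefaction_g} exceeds smallest observation "
            f"count {min_n}"
        )
    rows = []
    for (pop, locus), n in freqs.n.items():
        f = freqs.freqs(pop, locus)
        counts = (
            freqs.table[
                (freqs.table["population_id"] == pop) & (freqs.table["locus"] == locus)
            ]["count"]
            .to_numpy()
            .astype(int)
        )
        p2 = float(np.sum(f.values**2))
        A = len(f)
        Ae = 1.0 / p2
        He = n / (n - 1) * (1 - p2) if n > 1 else np.nan
        Ar = _rarefied_richness(counts, rarefaction_g)
        rows.append((pop, locus, n, A, Ae, Ar, He, He))
    per_locus = pd.DataFrame(
        rows, columns=["population_id", "locus", "n", "A", "Ae", "Ar", "He", "v"]
    )
    summary = (
        per_locus.groupby("population_id", sort=False)[["A", "Ae", "Ar", "He", "v"]]
        .mean()
        .reset_index()
    )
    return DiversityProfile(per_locus, summary, rarefaction_g)
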