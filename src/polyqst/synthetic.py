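"""Synthetic data with known truth for every pipeline stage.

Genotypes follow a Balding-Nichols island model: population allele
frequencies at each microsatellite locus are Dirichlet-distributed around
ancestral frequencies with spread set by a target F_ST, six allele copies
are drawn per individual, and only the set of distinct fragment lengths is
recorded — reproducing the dosage masking of real hexaploid data.

Phenotypes are the generative twin of the animal model: chamber effect +
population effect + additive values drawn conditional on the *realized*
marker kinship of the simulated genotypes (so model recovery is a fair
test, not a tautology of an assumed pedigree) + genotype-by-chamber
interaction (plasticity structure) + residual noise.

Defaults mirror the study conditions: 11-12 populations on a crossed
3 temperature x 4 precipitation grid, 25 genotypes per population, four
dinucleotide loci, four growth chambers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CHAMBERS, GenotypeTable, SiteTable, TEMPERATURE_CLASSES, TraitTable
from .popgen import KinshipMatrix, loiselle_kinship
from .quantgen import relationship_matrix

__all__ = [
    "LocusSpec",
    "SyntheticTruth",
    "DEFAULT_LOCI",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_grid_sites",
    "neutral_sigma_p2",
]


@dataclass(frozen=True)
class LocusSpec:
    name: str
    n_alleles: int
    repeat_length: int
    start_size: int


#: four loci shaped like the study's panel (allele counts 20/16/15/11)
DEFAULT_LOCI = (
    LocusSpec("B3-B8", 20, 2, 260),
    LocusSpec("HVM2", 16, 2, 100),
    LocusSpec("B4-D9", 15, 2, 230),
    LocusSpec("HVM3", 11, 2, 140),
)


@dataclass
class SyntheticTruth:
    """Everything that, with the seed, determines the generated tables."""

    seed: int
    fst_target: float | None = None
    ancestral_freqs: dict = field(default_factory=dict)
    population_freqs: dict = field(default_factory=dict)
    variance_spec: dict = field(default_factory=dict)  # trait -> (s2_p, s2_a, s2_e)
    sigma_gxe2: dict = field(default_factory=dict)
    chamber_effects: dict = field(default_factory=dict)
    true_qst: dict = field(default_factory=dict)  # trait -> {"printed":..,"textbook":..}


def neutral_sigma_p2(fst: float, sigma_a2: float) -> float:
    """Neutral-drift expectation of the between-population additive variance."""
    return 2.0 * fst / (1.0 - fst) * sigma_a2


def phenotype_frequency_moments(p: np.ndarray, ploidy: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Exact first two moments of within-individual allele frequencies.

    For ``ploidy`` iid allele copies drawn from frequencies ``p``, the
    recorded allelic phenotype is the support set S; the within-individual
    frequency of allele a is 1[a in S]/|S|.  Moments are computed exactly
    through the exponential generating function of the support:
    P(S = T) = ploidy! [x^ploidy] prod_{b in T} (e^{p_b x} - 1),
    accumulated by a symmetric-polynomial DP over alleles (support size and
    x-degree are both capped at ``ploidy``).

    Returns (E[1[a in S]/|S|], E[1[a in S]/|S|^2]) per allele.
    """
    p = np.asarray(p, float)
    A = len(p)
    d = ploidy + 1
    # g_b(x) = e^{p_b x} - 1 truncated at x^ploidy
    fact = np.array([math.factorial(j) for j in range(d)], float)
    gs = np.zeros((A, d))
    for b in range(A):
        gs[b, 1:] = p[b] ** np.arange(1, d) / fact[1:]
    # E[z, x] = prod_b (1 + z g_b(x)); E[k, j] is coeff of z^k x^j
    E = np.zeros((d, d))
    E[0, 0] = 1.0
    for b in range(A):
        shifted = np.zeros_like(E)
        for k in range(d - 1):
            shifted[k + 1] += _polymul_trunc(E[k], gs[b], d)
        E = E + shifted
    mu1 = np.zeros(A)
    mu2 = np.zeros(A)
    for a in range(A):
        # divide out this allele's factor: E_a = E / (1 + z g_a)
        Ea = np.zeros_like(E)
        for k in range(d):
            acc = E[k].copy()
            if k > 0:
                acc -= _polymul_trunc(Ea[k - 1], gs[a], d)
            Ea[k] = acc
        for k in range(1, d):
            # P(a in S, |S| = k) = ploidy! [x^ploidy] g_a(x) * e_{k-1}(others)
            coef = _polymul_trunc(gs[a], Ea[k - 1], d)[ploidy] * fact[ploidy]
            mu1[a] += coef / k
            mu2[a] += coef / k**2
    return mu1, mu2


def _polymul_trunc(a: np.ndarray, b: np.ndarray, d: int) -> np.ndarray:
    return np.convolve(a, b)[:d]


def fst_truth(truth: SyntheticTruth, ploidy: int = 6) -> float:
    """The differentiation the F_ST estimator targets under dosage masking.

    Gene-level F_ST is unidentifiable from allelic phenotypes, so the truth
    is defined on the observable scale: per locus and allele, the between-
    population variance (across the realized population frequencies) of the
    exact expected within-individual frequency mu_pa, over itself plus the
    mean within-population heterozygosity mu_pa(1 - mu_pa) — the estimand
    of the nested indicator ANOVA in ``fst_global``.
    """
    num = den = 0.0
    for locus, popfreqs in truth.population_freqs.items():
        pops = list(popfreqs)
        alleles = sorted(next(iter(popfreqs.values())).keys())
        mu = np.zeros((len(pops), len(alleles)))
        for i, p in enumerate(pops):
            freqs = np.array([popfreqs[p][a] for a in alleles])
            m1, _ = phenotype_frequency_moments(freqs, ploidy)
            mu[i] = m1
        s_b = mu.var(axis=0, ddof=1)
        s_w = (mu * (1 - mu)).mean(axis=0)
        num += s_b.sum()
        den += (s_b + s_w).sum()
    return num / den


def make_grid_sites(n_temp: int = 3, n_precip: int = 4, drop: str | None = None) -> SiteTable:
    """Crossed temperature x precipitation site grid (optionally one site dropped,
    emulating the excluded hexaploid-free alpine site)."""
    temps = TEMPERATURE_CLASSES[:n_temp]
    rows = [
        (f"{t}{p}", t, p)
        for t in temps
        for p in range(1, n_precip + 1)
    ]
    df = pd.DataFrame(rows, columns=["population_id", "temperature_class", "precipitation_class"])
    if drop is not None:
        if drop not in set(df["population_id"]):
            raise ValueError(f"cannot drop unknown site {drop!r}")
        df = df[df["population_id"] != drop].reset_index(drop=True)
    table = SiteTable(df)
    table.validate()
    return table


def simulate_genotypes(
    n_pop: int = 12,
    n_ind: int = 25,
    loci: tuple[LocusSpec, ...] = DEFAULT_LOCI,
    fst_target: float = 0.05,
    ploidy: int = 6,
    seed: int = 0,
    pop_ids: list[str] | None = None,
) -> tuple[GenotypeTable, SyntheticTruth]:
    """Balding-Nichols hexaploid genotypes with masked dosage.

    Population frequencies ~ Dirichlet(pbar * (1-F)/F); each individual
    receives ``ploidy`` allele copies and only the distinct fragment
    lengths survive into the table.
    """
    if not (0 < fst_target < 1):
        raise ValueError("fst_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if pop_ids is None:
        pop_ids = [f"POP{i+1:02d}" for i in range(n_pop)]
    if len(pop_ids) != n_pop:
        raise ValueError("pop_ids length must equal n_pop")
    truth = SyntheticTruth(seed=seed, fst_target=fst_target)
    scale = (1 - fst_target) / fst_target
    columns: dict[str, list] = {}
    for spec in loci:
        sizes = spec.start_size + spec.repeat_length * np.arange(spec.n_alleles)
        ancestral = rng.dirichlet(np.ones(spec.n_alleles))
        alpha = ancestral * scale
        if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
            raise ValueError("degenerate Dirichlet parameters")
        pop_freqs = {p: rng.dirichlet(alpha) for p in pop_ids}
        truth.ancestral_freqs[spec.name] = dict(zip(sizes.tolist(), ancestral.tolist()))
        truth.population_freqs[spec.name] = {
            p: dict(zip(sizes.tolist(), f.tolist())) for p, f in pop_freqs.items()
        }
        cells = []
        for p in pop_ids:
            draws = rng.multinomial(ploidy, pop_freqs[p], size=n_ind)
            for row in draws:
                cells.append(tuple(int(s) for s in sizes[row > 0]))
        columns[spec.name] = cells
    data = pd.DataFrame(
        {
            "individual_id": [f"{p}_i{j+1:02d}" for p in pop_ids for j in range(n_ind)],
            "population_id": [p for p in pop_ids for _ in range(n_ind)],
            **columns,
        }
    )
    table = GenotypeTable(data, {s.name: s.repeat_length for s in loci})
    table.validate()
    return table, truth


def simulate_phenotypes(
    g: GenotypeTable,
    variance_spec: dict[str, tuple[float, float, float]],
    chambers: tuple[str, ...] = CHAMBERS,
    sigma_gxe2: float | dict[str, float] = 0.0,
    chamber_effects: dict[str, float] | None = None,
    baseline: float = 10.0,
    seed: int = 0,
    kinship: KinshipMatrix | None = None,
) -> tuple[TraitTable, SyntheticTruth]:
    """Phenotypes from the animal-model generative process.

    ``variance_spec`` maps trait name -> (s2_p, s2_a, s2_e).  Additive
    values are MVN(0, 2G s2_a) with G the realized Loiselle kinship of
    ``g`` (PSD-clipped).  ``baseline`` keeps traits positive so the
    (max-min)/max plasticity index is defined.
    """
    for t, spec in variance_spec.items():
        if any(s < 0 for s in spec):
            raise ValueError(f"negative variance in spec for {t!r}")
    rng = np.random.default_rng(seed)
    G = kinship or loiselle_kinship(g)
    ids = list(g.individuals)
    A = relationship_matrix(G, ids)
    lam, Q = np.linalg.eigh(A)
    L = Q * np.sqrt(np.clip(lam, 0.0, None))
    pops = list(pd.unique(g.populations))
    pop_of = dict(zip(g.individuals, g.populations))
    if chamber_effects is None:
        chamber_effects = {c: 0.4 * k for k, c in enumerate(chambers)}
    gxe_spec = (
        {t: float(sigma_gxe2) for t in variance_spec}
        if np.isscalar(sigma_gxe2)
        else dict(sigma_gxe2)
    )
    truth = SyntheticTruth(
        seed=seed,
        variance_spec={t: tuple(map(float, s)) for t, s in variance_spec.items()},
        sigma_gxe2=gxe_spec,
        chamber_effects=dict(chamber_effects),
    )
    n = len(ids)
    rows = {
        "individual_id": [i for i in ids for _ in chambers],
        "chamber_id": [c for _ in ids for c in chambers],
    }
    for trait, (s2p, s2a, s2e) in variance_spec.items():
        pop_eff = dict(zip(pops, rng.normal(0.0, np.sqrt(s2p), len(pops))))
        a = L @ rng.normal(0.0, 1.0, n) * np.sqrt(s2a)
        s2g = gxe_spec.get(trait, 0.0)
        gxe = rng.normal(0.0, np.sqrt(s2g), (n, len(chambers))) if s2g > 0 else np.zeros((n, len(chambers)))
        eps = rng.normal(0.0, np.sqrt(s2e), (n, len(chambers)))
        y = []
        for i, ind in enumerate(ids):
            for k, c in enumerate(chambers):
                y.append(
                    baseline
                    + chamber_effects[c]
                    + pop_eff[pop_of[ind]]
                    + a[i]
                    + gxe[i, k]
                    + eps[i, k]
                )
        rows[trait] = y
        denom = s2p + s2a
        truth.true_qst[trait] = {
            "printed": s2p / denom if denom > 0 else np.nan,
            "textbook": s2p / (s2p + 2 * s2a) if (s2p + 2 * s2a) > 0 else np.nan,
        }
    table = TraitTable(pd.DataFrame(rows), tuple(variance_spec))
    table.validate()
    return table, truth
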