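import itertools

import numpy as np
import pandas as pd
import pytest

from polyqst.popgen import (
    allele_frequencies,
    bruvo_allele_distance,
    bruvo_distances,
    bruvo_set_distance,
    diversity_profile,
    fst_global,
    loiselle_kinship,
    rst_global,
)
from polyqst.synthetic import simulate_genotypes

from conftest import build_genotypes


# ---------------------------------------------------------------- frequencies
def test_allelic_phenotype_counting():
    g = build_genotypes(
        [("i1", "P1", {"L1": (100, 102)}), ("i2", "P1", {"L1": (100,)})], {"L1": 2}
    )
    f = allele_frequencies(g).freqs("P1", "L1")
    assert f[100] == pytest.approx(2 / 3)
    assert f[102] == pytest.approx(1 / 3)


def test_monomorphic_frequency_is_one():
    g = build_genotypes(
        [("i1", "P1", {"L1": (100,)}), ("i2", "P1", {"L1": (100,)})], {"L1": 2}
    )
    assert allele_frequencies(g).freqs("P1", "L1")[100] == 1.0


def test_frequencies_match_brute_force_enumeration(rng):
    # five individuals with random allele sets; oracle counts by direct loops
    alleles = [100, 102, 104, 106]
    rows = []
    for k in range(5):
        size = rng.integers(1, 4)
        cell = tuple(sorted(rng.choice(alleles, size=size, replace=False)))
        rows.append((f"i{k}", "P1", {"L1": cell}))
    g = build_genotypes(rows, {"L1": 2})
    counts = {}
    total = 0
    for _, _, cells in rows:
        for a in cells["L1"]:
            counts[a] = counts.get(a, 0) + 1
            total += 1
    f = allele_frequencies(g).freqs("P1", "L1")
    for a, c in counts.items():
        assert f[a] == pytest.approx(c / total, abs=1e-12)
    assert f.sum() == pytest.approx(1.0, abs=1e-12)


# ------------------------------------------------------------------- F_ST
def test_fst_fixed_differences_is_one():
    rows = [(f"a{k}", "P1", {"L1": (100,)}) for k in range(5)]
    rows += [(f"b{k}", "P2", {"L1": (104,)}) for k in range(5)]
    g = build_genotypes(rows, {"L1": 2})
    assert fst_global(g).value == pytest.approx(1.0)


def test_fst_identical_populations_near_zero(rng):
    # populations drawn from one frequency pool: estimates center on zero
    pool = [(100,), (100, 102), (102,), (100, 104), (104,), (102, 104)]
    vals = []
    for rep in range(20):
        rows = []
        for pop in ("P1", "P2"):
            picks = rng.integers(0, len(pool), size=10)
            rows += [(f"{pop}_{k}", pop, {"L1": pool[i]}) for k, i in enumerate(picks)]
        vals.append(fst_global(build_genotypes(rows, {"L1": 2})).value)
    assert abs(np.mean(vals)) < 0.03
    # exactly duplicated populations carry no positive differentiation signal
    rows = [(f"a{k}", "P1", {"L1": c}) for k, c in enumerate(pool)]
    rows += [(f"b{k}", "P2", {"L1": c}) for k, c in enumerate(pool)]
    assert fst_global(build_genotypes(rows, {"L1": 2})).value <= 0


def test_fst_monomorphic_undefined():
    rows = [(f"i{k}", "P1" if k < 3 else "P2", {"L1": (100,)}) for k in range(6)]
    g = build_genotypes(rows, {"L1": 2})
    res = fst_global(g)
    assert res.undefined and np.isnan(res.value)


def test_fst_rank_ordered_across_targets():
    means = []
    for target in (0.01, 0.05, 0.2):
        vals = [
            fst_global(
                simulate_genotypes(n_pop=8, n_ind=10, fst_target=target, seed=3000 + s)[0]
            ).value
            for s in range(8)
        ]
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_fst_jackknife_se_nonnegative(small_dataset):
    res = fst_global(small_dataset["genotypes"])
    assert res.se >= 0
    assert -0.05 < res.value < 1


# ------------------------------------------------------------------- R_ST
def test_rst_hand_anova_oracle():
    # sizes in repeat units: {10,10,12} vs {14,14,16}; one allele per individual
    rows = [(f"a{k}", "P1", {"L1": (s,)}) for k, s in enumerate((10, 10, 12))]
    rows += [(f"b{k}", "P2", {"L1": (s,)}) for k, s in enumerate((14, 14, 16))]
    g = build_genotypes(rows, {"L1": 1})
    # direct one-way ANOVA decomposition of the six size observations
    g1, g2 = np.array([10, 10, 12.0]), np.array([14, 14, 16.0])
    grand = np.concatenate([g1, g2]).mean()
    msa = sum(3 * (x.mean() - grand) ** 2 for x in (g1, g2)) / 1
    msw = (((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()) / 4
    nc = (6 - (9 + 9) / 6) / 1
    sb = (msa - msw) / nc
    expected = sb / (sb + msw)
    assert rst_global(g).value == pytest.approx(expected, abs=1e-12)


def test_rst_identical_size_distributions_centers_on_zero(rng):
    pool = [(10,), (12,), (10,), (14,), (12, 14)]
    vals = []
    for rep in range(20):
        rows = []
        for pop in ("P1", "P2"):
            picks = rng.integers(0, len(pool), size=10)
            rows += [(f"{pop}_{k}", pop, {"L1": pool[i]}) for k, i in enumerate(picks)]
        vals.append(rst_global(build_genotypes(rows, {"L1": 1})).value)
    assert abs(np.mean(vals)) < 0.04
    rows = [(f"a{k}", "P1", {"L1": c}) for k, c in enumerate(pool)]
    rows += [(f"b{k}", "P2", {"L1": c}) for k, c in enumerate(pool)]
    assert rst_global(build_genotypes(rows, {"L1": 1})).value <= 0


def test_rst_fixed_size_difference_is_one():
    rows = [(f"a{k}", "P1", {"L1": (10,)}) for k in range(4)]
    rows += [(f"b{k}", "P2", {"L1": (12,)}) for k in range(4)]
    g = build_genotypes(rows, {"L1": 1})
    assert rst_global(g).value == pytest.approx(1.0)


# ------------------------------------------------------------------ kinship
def _loiselle_oracle(g):
    """Direct double-sum evaluation of the default kinship estimator."""
    N = len(g.data)
    num = np.zeros((N, N))
    den = np.zeros((N, N))
    for locus in g.loci:
        cells = list(g.data[locus])
        alleles = sorted({a for c in cells if c is not None for a in c})
        idx = [i for i, c in enumerate(cells) if c is not None]
        P = {}
        for i in idx:
            P[i] = {a: (1.0 / len(cells[i]) if a in cells[i] else 0.0) for a in alleles}
        n_l = len(idx)
        pbar = {a: np.mean([P[i][a] for i in idx]) for a in alleles}
        var = {a: np.mean([(P[i][a] - pbar[a]) ** 2 for i in idx]) for a in alleles}
        corr = sum(var[a] for a in alleles) / (n_l - 1)
        d = sum(pbar[a] * (1 - pbar[a]) for a in alleles)
        for i in idx:
            for j in idx:
                s = sum((P[i][a] - pbar[a]) * (P[j][a] - pbar[a]) for a in alleles)
                num[i, j] += s + corr
                den[i, j] += d
    return num / den


def test_loiselle_matches_double_sum_oracle(toy_genotypes):
    kin = loiselle_kinship(toy_genotypes)
    oracle = _loiselle_oracle(toy_genotypes)
    np.testing.assert_allclose(kin.values, oracle, atol=1e-10)


def test_loiselle_identical_individuals_agree_with_oracle():
    rows = [
        ("i1", "P1", {"L1": (100, 102), "L2": (200,)}),
        ("i2", "P1", {"L1": (100, 102), "L2": (200,)}),
        ("i3", "P2", {"L1": (104,), "L2": (204, 208)}),
    ]
    g = build_genotypes(rows, {"L1": 2, "L2": 4})
    kin = loiselle_kinship(g)
    oracle = _loiselle_oracle(g)
    assert kin.values[0, 1] == pytest.approx(oracle[0, 1], abs=1e-12)
    assert kin.values[0, 1] > kin.values[0, 2]


def test_loiselle_mean_offdiagonal_identity(rng):
    # exact zero-mean identity of the frequency-centered estimator
    for trial in range(3):
        n = 8
        rows = []
        for k in range(n):
            cell1 = tuple(sorted(rng.choice([100, 102, 104, 106], rng.integers(1, 4), replace=False)))
            cell2 = tuple(sorted(rng.choice([200, 204], rng.integers(1, 3), replace=False)))
            rows.append((f"i{k}", "P1" if k < 4 else "P2", {"L1": cell1, "L2": cell2}))
        g = build_genotypes(rows, {"L1": 2, "L2": 4})
        kin = loiselle_kinship(g)
        off = kin.values[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 1e-10


def test_loiselle_permutation_equivariance(toy_genotypes):
    kin = loiselle_kinship(toy_genotypes)
    perm = [3, 1, 4, 0, 5, 2]
    g2 = toy_genotypes
    g2 = type(g2)(g2.data.iloc[perm].reset_index(drop=True), dict(g2.repeat_lengths))
    kin2 = loiselle_kinship(g2)
    np.testing.assert_allclose(kin2.values, kin.values[np.ix_(perm, perm)], atol=1e-12)


# -------------------------------------------------------------------- Bruvo
def test_bruvo_closed_forms():
    assert bruvo_allele_distance(100, 102, 2) == pytest.approx(0.5)
    assert bruvo_set_distance((100,), (100,), 2) == 0.0
    assert bruvo_set_distance((100, 164), (100, 164), 2) == 0.0


def test_bruvo_equal_size_matching_oracle():
    # {160,164} vs {160,168}, repeat 4: enumerate both assignments directly
    d = bruvo_set_distance((160, 164), (160, 168), 4)
    costs = []
    for perm in itertools.permutations((160, 168)):
        costs.append(
            np.mean([bruvo_allele_distance(x, y, 4) for x, y in zip((160, 164), perm)])
        )
    assert d == pytest.approx(min(costs), abs=1e-12)
    assert d == pytest.approx(0.25)


def test_bruvo_fillin_enumeration_oracle():
    # unequal set sizes: oracle enumerates genome-addition fill-ins + matchings
    a, b, rep = (100, 104), (100, 102, 106), 2

    def oracle(a, b, rep):
        if len(a) > len(b):
            a, b = b, a
        k = len(b)
        best = np.inf
        for fill in itertools.combinations_with_replacement(a, k - len(a)):
            padded = list(a) + list(fill)
            for perm in itertools.permutations(b):
                cost = np.mean([bruvo_allele_distance(x, y, rep) for x, y in zip(padded, perm)])
                best = min(best, cost)
        return best

    assert bruvo_set_distance(a, b, rep) == pytest.approx(oracle(a, b, rep), abs=1e-10)


def test_bruvo_matrix_invariants(small_dataset):
    D = bruvo_distances(small_dataset["genotypes"]).to_numpy()
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)
    assert D.min() >= 0 and D.max() < 1


# ---------------------------------------------------------------- diversity
def test_diversity_monomorphic():
    rows = [(f"i{k}", "P1", {"L1": (100,)}) for k in range(5)]
    g = build_genotypes(rows, {"L1": 2})
    prof = diversity_profile(g, 3)
    row = prof.per_locus.iloc[0]
    assert row["A"] == 1 and row["Ae"] == pytest.approx(1.0)
    assert row["He"] == pytest.approx(0.0) and row["v"] == pytest.approx(0.0)


def test_diversity_two_equifrequent_alleles_limit():
    rows = [(f"i{k}", "P1", {"L1": (100,) if k % 2 else (102,)}) for k in range(40)]
    g = build_genotypes(rows, {"L1": 2})
    row = diversity_profile(g, 2).per_locus.iloc[0]
    assert row["Ae"] == pytest.approx(2.0)
    assert row["He"] == pytest.approx(0.5, abs=0.02)


def test_rarefied_richness_matches_exhaustive_subsampling():
    # six observations with counts (3, 2, 1); oracle averages over all C(6,3) subsets
    rows = [
        ("i1", "P1", {"L1": (100,)}),
        ("i2", "P1", {"L1": (100,)}),
        ("i3", "P1", {"L1": (100, 102)}),
        ("i4", "P1", {"L1": (102, 104)}),
    ]
    g = build_genotypes(rows, {"L1": 2})
    gsub = 3
    obs = [100, 100, 100, 102, 102, 104]
    expected = np.mean(
        [len(set(c)) for c in itertools.combinations(obs, gsub)]
    )
    row = diversity_profile(g, gsub).per_locus.iloc[0]
    assert row["Ar"] == pytest.approx(expected, abs=1e-10)


def test_rarefaction_size_validation(toy_genotypes):
    with pytest.raises(ValueError):
        diversity_profile(toy_genotypes, 1)
    with pytest.raises(ValueError):
        diversity_profile(toy_genotypes, 10_000)
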