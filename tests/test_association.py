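import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyqst.association import (
    allele_filter,
    diversity_trait_correlation,
    mantel,
    manova_stepwise,
    pillai_trace_test,
    ztransform,
)
from polyqst.popgen import diversity_profile
from polyqst.synthetic import simulate_genotypes

from conftest import build_genotypes


def _dist(values, ids):
    d = np.asarray(values, float)
    return pd.DataFrame(d, index=ids, columns=ids)


def _random_dist(rng, n, ids=None):
    ids = ids or [f"i{k}" for k in range(n)]
    x = rng.normal(0, 1, (n, 3))
    from scipy.spatial.distance import pdist, squareform

    return pd.DataFrame(squareform(pdist(x)), index=ids, columns=ids)


# -------------------------------------------------------------------- Mantel
def test_mantel_scale_invariance(rng):
    d1 = _random_dist(rng, 8)
    res = mantel(d1, 2.0 * d1, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)


def test_mantel_label_mismatch_error(rng):
    d1 = _random_dist(rng, 6)
    d2 = _random_dist(rng, 6, ids=[f"x{k}" for k in range(6)])
    with pytest.raises(ValueError):
        mantel(d1, d2)


def test_mantel_exact_enumeration_matches_oracle(rng):
    n = 5
    d1, d2 = _random_dist(rng, n), _random_dist(rng, n)
    res = mantel(d1, d2, n_perm="exact")
    iu = np.triu_indices(n, 1)
    v1, v2 = d1.to_numpy()[iu], d2.to_numpy()[iu]
    r_oracle = np.corrcoef(v1, v2)[0, 1]
    assert res.r == pytest.approx(r_oracle, abs=1e-10)
    count = 0
    total = 0
    a1 = d1.to_numpy()
    for perm in itertools.permutations(range(n)):
        if perm == tuple(range(n)):
            continue
        idx = np.array(perm)
        rp = np.corrcoef(a1[np.ix_(idx, idx)][iu], v2)[0, 1]
        count += rp >= r_oracle
        total += 1
    assert res.p_value == pytest.approx((1 + count) / (total + 1), abs=1e-12)


def test_mantel_agrees_with_skbio(rng):
    from skbio import DistanceMatrix
    from skbio.stats.distance import mantel as skbio_mantel

    n = 12
    ids = [f"i{k}" for k in range(n)]
    d1, d2 = _random_dist(rng, n, ids), _random_dist(rng, n, ids)
    res = mantel(d1, d2, n_perm=999, seed=0)
    r_sk, p_sk, _ = skbio_mantel(
        DistanceMatrix(d1.to_numpy(), ids),
        DistanceMatrix(d2.to_numpy(), ids),
        method="pearson",
        permutations=999,
        alternative="greater",
    )
    assert res.r == pytest.approx(r_sk, abs=1e-10)
    assert res.p_value == pytest.approx(p_sk, abs=0.08)


def test_partial_mantel_zero_conditioning_equals_plain(rng):
    d1, d2 = _random_dist(rng, 8), _random_dist(rng, 8)
    zero = _dist(np.zeros((8, 8)), list(d1.index))
    plain = mantel(d1, d2, n_perm=99, seed=1)
    partial = mantel(d1, d2, n_perm=99, seed=1, conditioning=zero)
    assert partial.partial
    assert partial.r == pytest.approx(plain.r, abs=1e-12)
    assert partial.p_value == pytest.approx(plain.p_value, abs=1e-12)


def test_mantel_null_p_uniformity(rng):
    ps = []
    for s in range(80):
        r2 = np.random.default_rng(5000 + s)
        ps.append(mantel(_random_dist(r2, 10), _random_dist(r2, 10), n_perm=99, seed=s).p_value)
    ps = np.array(ps)
    assert 0.35 < ps.mean() < 0.65
    assert (ps <= 0.05).mean() < 0.15


def test_mantel_relabeling_invariance(rng):
    d1, d2 = _random_dist(rng, 7), _random_dist(rng, 7)
    perm = np.array([3, 0, 6, 2, 5, 1, 4])
    ids = list(d1.index)
    new_ids = [ids[i] for i in perm]
    d1p = d1.iloc[perm, perm]
    d2p = d2.iloc[perm, perm]
    assert mantel(d1p, d2p, n_perm=49, seed=0).r == pytest.approx(
        mantel(d1, d2, n_perm=49, seed=0).r, abs=1e-12
    )


# ------------------------------------------------- diversity correlations
def test_correlation_matches_hand_formula(rng):
    g, _ = simulate_genotypes(n_pop=11, n_ind=6, fst_target=0.1, seed=77)
    div = diversity_profile(g, 5)
    pops = div.summary["population_id"]
    x = div.summary["v"].to_numpy()
    y = 2.0 * x + rng.normal(0, 0.05 * x.std(), len(x))
    means = pd.DataFrame({"trait": y}, index=pops)
    out = diversity_trait_correlation(div, means)
    sx, sy = x - x.mean(), y - y.mean()
    r_hand = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
    t = r_hand * np.sqrt((len(x) - 2) / (1 - r_hand**2))
    p_hand = 2 * stats.t.sf(abs(t), len(x) - 2)
    row = out.iloc[0]
    assert row["r"] == pytest.approx(r_hand, abs=1e-10)
    assert row["p"] == pytest.approx(p_hand, abs=1e-10)
    assert row["n"] == 11


def test_correlation_zero_variance_is_na(rng):
    g, _ = simulate_genotypes(n_pop=5, n_ind=6, fst_target=0.1, seed=78)
    div = diversity_profile(g, 5)
    means = pd.DataFrame(
        {"flat": np.ones(5)}, index=div.summary["population_id"]
    )
    with pytest.warns(UserWarning):
        out = diversity_trait_correlation(div, means)
    assert np.isnan(out.iloc[0]["r"])


# ------------------------------------------------------------ allele screen
def test_allele_filter_rules():
    # 8 populations of 25; allele patterns constructed per rule
    rows = []
    for p in range(8):
        pop = f"P{p+1}"
        for k in range(25):
            cell = [100]  # carried by everyone: near-fixed
            if k == 0:
                cell.append(102)  # present in all 8 populations
            if p < 3 and k < 1:
                cell.append(104)  # 3 pops, count frequency 1/27 < 0.05
            rows.append((f"{pop}_{k}", pop, {"L1": tuple(sorted(set(cell)))}))
    g = build_genotypes(rows, {"L1": 2})
    screen = allele_filter(g)
    tab = screen.table.set_index("allele")
    assert not tab.loc[100, "kept"] and tab.loc[100, "reason"] == "near-fixation"
    assert tab.loc[102, "kept"]  # present in 8 >= 7 populations
    assert not tab.loc[104, "kept"] and tab.loc[104, "reason"] == "rare/private"
    # every input allele classified exactly once
    assert set(screen.table["allele"]) == {100, 102, 104}


def test_allele_filter_rare_but_common_somewhere_kept():
    rows = []
    for p in range(8):
        pop = f"P{p+1}"
        for k in range(10):
            cell = (100, 104) if (p == 0 and k < 5) else (100, 102)
            rows.append((f"{pop}_{k}", pop, {"L1": cell}))
    g = build_genotypes(rows, {"L1": 2})
    tab = allele_filter(g).table.set_index("allele")
    # allele 104: one population only, frequency 5/20 = 0.25 > 0.05 -> kept
    assert tab.loc[104, "kept"]
    assert tab.loc[104, "n_pops"] == 1


def test_filter_partition(small_dataset):
    g = small_dataset["genotypes"]
    screen = allele_filter(g)
    all_alleles = {(l, a) for l in g.loci for c in g.data[l] if c for a in c}
    classified = set(zip(screen.table["locus"], screen.table["allele"]))
    assert classified == all_alleles
    kept = screen.table["kept"].sum()
    assert kept + (~screen.table["kept"]).sum() == len(screen.table)


# ----------------------------------------------------------------- MANOVA
def test_ztransform_moments(rng):
    df = pd.DataFrame(rng.normal(3, 5, (30, 4)))
    z = ztransform(df)
    assert np.allclose(z.mean(), 0, atol=1e-12)
    assert np.allclose(z.std(ddof=1), 1, atol=1e-12)


def test_pillai_matches_canonical_eigenvalue_oracle(rng):
    n, p = 24, 3
    Y = rng.normal(0, 1, (n, p))
    x = rng.integers(0, 2, n).astype(float)
    X0 = np.ones((n, 1))
    V, F, df1, df2, pval = pillai_trace_test(Y, X0, x[:, None])
    # oracle: Pillai = sum of eigenvalues of H(H+E)^-1 via direct SSCPs
    X_full = np.column_stack([X0, x])
    B_full = np.linalg.lstsq(X_full, Y, rcond=None)[0]
    E = (Y - X_full @ B_full).T @ (Y - X_full @ B_full)
    B_red = np.linalg.lstsq(X0, Y, rcond=None)[0]
    H = (Y - X0 @ B_red).T @ (Y - X0 @ B_red) - E
    eig = np.linalg.eigvals(H @ np.linalg.inv(H + E)).real
    assert V == pytest.approx(float(np.sum(eig)), abs=1e-10)
    assert 0 <= V <= min(p, 1)


def test_pillai_matches_statsmodels(rng):
    from statsmodels.multivariate.manova import MANOVA

    n, p = 40, 3
    Y = rng.normal(0, 1, (n, p))
    x = rng.integers(0, 2, n).astype(float)
    Y[:, 0] += 0.8 * x
    V, F, df1, df2, pval = pillai_trace_test(Y, np.ones((n, 1)), x[:, None])
    df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
    df["x"] = x
    mv = MANOVA.from_formula("y1 + y2 + y3 ~ x", data=df)
    tab = mv.mv_test().results["x"]["stat"]
    assert V == pytest.approx(float(tab.loc["Pillai's trace", "Value"]), abs=1e-8)
    assert pval == pytest.approx(float(tab.loc["Pillai's trace", "Pr > F"]), abs=1e-8)


def _random_screen_design(rng, n_geno, effects=None):
    """Synthetic single-locus genotype table with controllable allele effects."""
    pops = [f"P{p+1}" for p in range(8)]
    alleles = [100, 102, 104, 106]
    rows = []
    for k in range(n_geno):
        pop = pops[k % len(pops)]
        size = rng.integers(1, 4)
        cell = tuple(sorted(rng.choice(alleles, size=size, replace=False)))
        rows.append((f"g{k}", pop, {"L1": cell}))
    g = build_genotypes(rows, {"L1": 2})
    presence = {
        a: np.array([float(a in c) for c in g.data["L1"]]) for a in alleles
    }
    Y = rng.normal(0, 1, (n_geno, 3))
    if effects:
        for a, (cols, size) in effects.items():
            for c in cols:
                Y[:, c] += size * presence[a]
    traits = pd.DataFrame(Y, index=[f"g{k}" for k in range(n_geno)],
                          columns=["t1", "t2", "t3"])
    return g, traits


def test_manova_detects_injected_allele_effect(rng):
    hits = 0
    n_runs = 100
    for s in range(n_runs):
        r2 = np.random.default_rng(9000 + s)
        g, traits = _random_screen_design(r2, 60, effects={102: ([0, 1], 1.0)})
        screen = allele_filter(g, presence_min_pops=1, freq_threshold=0.0)
        res = manova_stepwise(traits, screen, g, alpha_enter=0.05, n_order_perm=24, seed=s)
        if "L1_102" in res.retained:
            hits += 1
    assert hits >= 90


def test_manova_null_retention_near_alpha(rng):
    alpha = 0.05
    retained = 0
    tested = 0
    for s in range(500):
        r2 = np.random.default_rng(40_000 + s)
        g, traits = _random_screen_design(r2, 50)
        screen = allele_filter(g, presence_min_pops=1, freq_threshold=0.0)
        res = manova_stepwise(traits, screen, g, alpha_enter=alpha, n_order_perm=1, seed=s)
        n_candidates = screen.table["kept"].sum()
        tested += n_candidates
        retained += len(res.retained)
    rate = retained / tested
    assert rate == pytest.approx(alpha, abs=0.02)


def test_manova_pillai_bounds_on_joint_fit(small_dataset, rng):
    g = small_dataset["genotypes"]
    traits = small_dataset["traits"]
    means = traits.data.groupby("individual_id", sort=False)[
        list(traits.trait_names)
    ].mean()
    screen = allele_filter(g)
    res = manova_stepwise(means, screen, g, alpha_enter=0.2, n_order_perm=10, seed=1)
    p_dim = means.shape[1]
    for _, row in res.joint.iterrows():
        assert 0 <= row["pillai"] <= min(p_dim, 1)
        assert row["p_worst_order"] >= row["p_sequential"] - 1e-12
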