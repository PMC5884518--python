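"""End-to-end orchestration of the differentiation analysis.

``run_all`` executes: plasticity -> allele frequencies / kinship / F_ST /
R_ST -> per-trait P_ST and Q_ST (values and plasticities) -> simulated
neutral Q_ST-F_ST and Q_ST-R_ST tests -> co-inertia of trait means (and
plasticities) vs markers with climate/locality ANOVA and Tukey letters ->
Mantel / partial Mantel -> diversity-trait correlations -> allele screen +
stepwise MANOVA.  One integer seed governs every stochastic stage through a
documented per-stage derivation; a manifest records config and seed so a
rerun is byte-identical.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .association import allele_filter, diversity_trait_correlation, mantel, manova_stepwise
from .data_io import (
    GenotypeTable,
    SiteTable,
    TraitTable,
    read_genotypes,
    read_sites,
    read_traits,
    write_results,
)
from .multivariate import axis_climate_anova, coinertia, ordinate, trait_mean_table
from .neutrality import combined_df_b, effective_df, simulate_neutral_null, qst_fst_test
from .popgen import (
    allele_frequencies,
    bruvo_distances,
    diversity_profile,
    fst_global,
    loiselle_kinship,
    rst_global,
)
from .quantgen import (
    NonConvergenceError,
    fit_animal_model,
    fit_population_model,
    plasticity_index,
    pst,
    qst,
)

log = logging.getLogger("polyqst")

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(seed: int, tag: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage tag folded into the
    run seed, kept below 2^31."""
    return (int(seed) ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF


@dataclass
class RunConfig:
    genotypes: str | GenotypeTable = ""
    traits: str | TraitTable = ""
    sites: str | SiteTable = ""
    out_dir: str | None = None
    seed: int = 0
    qst_variant: str = "printed"
    pst_variant: str = "brommer"
    marker_distance: str = "bruvo"
    null_reps: int = 20_000
    n_perm: int = 999
    manova_order_perm: int = 5000
    rarefaction_g: int | None = None
    fst_floor: float = 1e-4
    force: bool = False

    def serializable(self) -> dict:
        d = asdict(self)
        for key in ("genotypes", "traits", "sites"):
            if not isinstance(d[key], str):
                d[key] = f"<in-memory {type(d[key]).__name__}>"
        return d


def _load(cfg: RunConfig) -> tuple[GenotypeTable, TraitTable, SiteTable]:
    g = cfg.genotypes if isinstance(cfg.genotypes, GenotypeTable) else read_genotypes(cfg.genotypes)
    t = cfg.traits if isinstance(cfg.traits, TraitTable) else read_traits(cfg.traits)
    s = cfg.sites if isinstance(cfg.sites, SiteTable) else read_sites(cfg.sites)
    g.validate()
    t.validate()
    s.validate(g)
    return g, t, s


def _differentiation_row(trait, kind, fit_pop, fit_anim, fst, rst, cfg, n_pop, df_a):
    """One Table-2-shaped record: P_ST, Q_ST and their neutrality tests."""
    out = {"trait": trait, "kind": kind, "n_pop": n_pop, "df_a": df_a}
    p_est = pst(fit_pop, variant=cfg.pst_variant, trait=trait) if fit_pop else None
    q_est = qst(fit_anim, variant=cfg.qst_variant, trait=trait) if fit_anim else None
    p_variant = "textbook" if cfg.pst_variant == "brommer" else "printed"
    fst_base = max(fst.value, cfg.fst_floor)
    if p_est is not None and not p_est.is_na:
        out["pst"] = p_est.value
        out["pst_se"] = p_est.se
        sw = fit_pop.components["sigma_w2"]
        null = simulate_neutral_null(
            fst_base,
            max(sw, 1e-12),
            n_pop=n_pop,
            n_loci=max(len(fst.per_locus), 1),
            df_a=effective_df(sw, fit_pop.se["sigma_w2"]) or max(fit_pop.n_obs - n_pop, 1),
            reps=cfg.null_reps,
            seed=stage_seed(cfg.seed, f"pstnull:{kind}:{trait}"),
            qst_variant=p_variant,
            df_b=combined_df_b(
                fit_pop.components["sigma_b2"], fit_pop.se["sigma_b2"], n_pop - 1
            ),
        )
        out["pst_fst_p"] = qst_fst_test(p_est, fst, null).p_value
    else:
        out["pst"] = out["pst_se"] = out["pst_fst_p"] = np.nan
    if q_est is not None and not q_est.is_na:
        out["qst"] = q_est.value
        out["qst_se"] = q_est.se
        for base, name in ((fst, "fst"), (rst, "rst")):
            base_val = max(base.value, cfg.fst_floor) if np.isfinite(base.value) else np.nan
            if not np.isfinite(base_val):
                out[f"qst_{name}_p"] = np.nan
                continue
            sa = fit_anim.components["sigma_a2"]
            null = simulate_neutral_null(
                base_val,
                max(sa, 1e-12),
                n_pop=n_pop,
                n_loci=max(len(base.per_locus), 1),
                df_a=effective_df(sa, fit_anim.se["sigma_a2"]) or max(df_a, 1),
                reps=cfg.null_reps,
                seed=stage_seed(cfg.seed, f"qstnull:{name}:{kind}:{trait}"),
                qst_variant=cfg.qst_variant,
                df_b=combined_df_b(
                    fit_anim.components["sigma_p2"], fit_anim.se["sigma_p2"], n_pop - 1
                ),
            )
            out[f"qst_{name}_p"] = qst_fst_test(q_est, base, null).p_value
    else:
        out["qst"] = out["qst_se"] = out["qst_fst_p"] = out["qst_rst_p"] = np.nan
        if q_est is not None:
            out["qst_na_reason"] = q_est.na_reason
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run the whole pipeline; returns a dict of result objects and tables."""
    g, traits, sites = _load(cfg)
    results: dict = {"config": cfg.serializable()}
    trait_names = list(traits.trait_names)
    n_pop = g.data["population_id"].nunique()
    n_geno = len(g.data)
    df_a = max(n_geno - n_pop, 1)

    log.info("stage: plasticity")
    plast = plasticity_index(traits)
    results["plasticity"] = plast

    log.info("stage: marker statistics")
    freqs = allele_frequencies(g)
    kin = loiselle_kinship(g)
    fst = fst_global(g)
    rst = rst_global(g)
    D_bruvo = bruvo_distances(g)
    results.update(freqs=freqs, kinship=kin, fst=fst, rst=rst, bruvo=D_bruvo)
    if fst.undefined:
        raise RuntimeError("stage diffstats: F_ST undefined (all loci monomorphic)")

    log.info("stage: variance components and differentiation indices")
    tdata = traits.data
    rows = []
    for trait in trait_names:
        record_sets = {
            "value": (
                tdata[trait].to_numpy(float),
                tdata["chamber_id"].to_numpy(),
                tdata["individual_id"].map(
                    dict(zip(g.individuals, g.populations))
                ).to_numpy(),
                tdata["individual_id"].to_numpy(),
            ),
            "plasticity": (
                plast.data[trait].to_numpy(float),
                None,
                pd.Series(plast.data.index).map(
                    dict(zip(g.individuals, g.populations))
                ).to_numpy(),
                plast.data.index.to_numpy(),
            ),
        }
        for kind, (y, chamber, pop, ind) in record_sets.items():
            fit_pop = fit_anim = None
            try:
                fit_pop = fit_population_model(y, chamber, pop)
            except (ValueError, NonConvergenceError) as exc:
                warnings.warn(f"population model failed for {trait}/{kind}: {exc}")
            try:
                fit_anim = fit_animal_model(y, chamber, pop, ind, kin)
            except (ValueError, NonConvergenceError) as exc:
                warnings.warn(f"animal model failed for {trait}/{kind}: {exc}")
            rows.append(
                _differentiation_row(trait, kind, fit_pop, fit_anim, fst, rst, cfg, n_pop, df_a)
            )
    differentiation = pd.DataFrame(rows)
    results["differentiation"] = differentiation

    log.info("stage: co-inertia")
    means_z = trait_mean_table(traits)
    marker_scores = ordinate(D_bruvo, n_axes=2, source="markers")
    coa = {}
    climate = {}
    for tag, matrix in (("mean", means_z), ("plast", plast.data.dropna())):
        common = [i for i in matrix.index if i in marker_scores.scores.index]
        tr_scores = ordinate(matrix.loc[common], n_axes=2, source="traits")
        mk = ordinate(D_bruvo.loc[common, common], n_axes=2, source="markers")
        res = coinertia(
            tr_scores, mk, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, f"coa:{tag}")
        )
        coa[tag] = res
        pops = pd.Series(common).map(dict(zip(g.individuals, g.populations)))
        climate[tag] = axis_climate_anova(res.projections_a["coa1"], pops, sites)
    results["coinertia"] = coa
    results["climate_anova"] = climate

    log.info("stage: Mantel tests")
    site_df = sites.data.set_index("population_id")
    tnum = dict(zip(sites.data["population_id"], sites.temperature_code()))
    env = pd.DataFrame(
        {
            "t": [tnum[p] for p in g.populations],
            "p": [site_df.loc[p, "precipitation_class"] for p in g.populations],
        },
        index=list(g.individuals),
    ).astype(float)
    env = (env - env.mean()) / env.std(ddof=1)
    from scipy.spatial.distance import pdist, squareform

    env_d = pd.DataFrame(
        squareform(pdist(env.to_numpy())), index=env.index, columns=env.index
    )
    mantel_rows = []
    m_env = mantel(
        env_d, D_bruvo, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "mantel:env")
    )
    mantel_rows.append(("environment", "none", m_env.r, m_env.p_value, m_env.n_perm))
    geo_available = {"lon", "lat"} <= set(sites.data.columns)
    if geo_available:
        from .geo import great_circle_matrix

        geo_d = great_circle_matrix(sites, list(g.individuals), list(g.populations))
        m_geo = mantel(
            geo_d, D_bruvo, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "mantel:geo")
        )
        mantel_rows.append(("geography", "none", m_geo.r, m_geo.p_value, m_geo.n_perm))
        m_env_geo = mantel(
            env_d, D_bruvo, n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, "mantel:env|geo"), conditioning=geo_d,
        )
        mantel_rows.append(
            ("environment", "geography", m_env_geo.r, m_env_geo.p_value, m_env_geo.n_perm)
        )
        m_geo_env = mantel(
            geo_d, D_bruvo, n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, "mantel:geo|env"), conditioning=env_d,
        )
        mantel_rows.append(
            ("geography", "environment", m_geo_env.r, m_geo_env.p_value, m_geo_env.n_perm)
        )
    else:
        log.info("site table has no lon/lat: geographic Mantel (IBD) skipped")
    mantel_table = pd.DataFrame(
        mantel_rows, columns=["distance", "conditioning", "r", "p", "n_perm"]
    )
    results["mantel"] = mantel_table

    log.info("stage: diversity correlations")
    g_min = min(freqs.n.values())
    rare_g = cfg.rarefaction_g or max(2, min(g_min, 20))
    div = diversity_profile(g, rare_g)
    pop_of = dict(zip(g.individuals, g.populations))
    raw_means = traits.data.groupby("individual_id", sort=False)[trait_names].mean()
    pop_means = raw_means.groupby(raw_means.index.map(pop_of)).mean()
    pop_plast = plast.data.groupby(plast.data.index.map(pop_of)).mean()
    corr_means = diversity_trait_correlation(div, pop_means)
    corr_plast = diversity_trait_correlation(div, pop_plast)
    corr_means["kind"] = "value"
    corr_plast["kind"] = "plasticity"
    diversity_corr = pd.concat([corr_means, corr_plast], ignore_index=True)
    results["diversity"] = div
    results["diversity_correlations"] = diversity_corr

    log.info("stage: allele screen + MANOVA")
    screen = allele_filter(g, freqs)
    try:
        man = manova_stepwise(
            raw_means,
            screen,
            g,
            alpha_enter=0.05,
            n_order_perm=cfg.manova_order_perm,
            seed=stage_seed(cfg.seed, "manova"),
        )
    except ValueError as exc:
        warnings.warn(f"MANOVA stage skipped: {exc}")
        man = None
    results["allele_screen"] = screen
    results["manova"] = man

    if cfg.out_dir:
        _write_reports(cfg, results, fst, rst, coa, climate, differentiation)
    return results


def _coa_report(coa, climate) -> pd.DataFrame:
    rows = []
    for tag in coa:
        res, cl = coa[tag], climate[tag]
        rows.append((f"COA{tag}", "RV", np.nan, res.rv, res.p_value, np.nan))
        for _, r in cl.environment.iterrows():
            if r["term"] == "Residual":
                continue
            rows.append((f"COA{tag}", r["term"], r["df"], r["F"], r["p"], r["explained_pct"]))
        loc = cl.locality[cl.locality["term"] != "Residual"].iloc[0]
        rows.append((f"COA{tag}", "Locality", loc["df"], loc["F"], loc["p"], loc["explained_pct"]))
    return pd.DataFrame(
        rows, columns=["analysis", "term", "df", "statistic", "p", "explained_pct"]
    )


def _write_reports(cfg, results, fst, rst, coa, climate, differentiation) -> None:
    tables = {
        "differentiation": differentiation,
        "global_indices": pd.DataFrame(
            {
                "index": ["F_ST", "R_ST"],
                "value": [fst.value, rst.value],
                "se": [fst.se, rst.se],
            }
        ),
        "coinertia": _coa_report(coa, climate),
        "tukey_letters": pd.DataFrame(
            [
                (tag, pop, letters)
                for tag, cl in climate.items()
                for pop, letters in cl.letters.items()
            ],
            columns=["analysis", "population_id", "letters"],
        ),
        "mantel": results["mantel"],
        "diversity": results["diversity"].summary,
        "diversity_correlations": results["diversity_correlations"],
        "allele_screen": results["allele_screen"].table,
    }
    if results["manova"] is not None:
        tables["manova_joint"] = results["manova"].joint
        if results["manova"].slopes is not None:
            tables["manova_slopes"] = results["manova"].slopes.reset_index(names="allele")
    manifest = {
        "config": results["config"],
        "seed": cfg.seed,
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    write_results(tables, cfg.out_dir, manifest=manifest, force=cfg.force)
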