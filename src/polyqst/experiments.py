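"""Simulation studies of the pipeline's statistical properties.

Each driver simulates data with known truth through :mod:`polyqst.synthetic`,
runs the estimation pipeline, and summarizes calibration or recovery.  They
back both the acceptance checks and the reproducibility script; problem
sizes default to scaled-down versions of the study design (11 populations,
four loci, four growth chambers) so a full run stays in the minutes range.
"""

from __future__ import annotations

import numpy as np

from .neutrality import combined_df_b, effective_df, qst_fst_test, simulate_neutral_null
from .popgen import fst_global, loiselle_kinship
from .quantgen import NonConvergenceError, fit_animal_model, qst
from .synthetic import (
    fst_truth,
    neutral_sigma_p2,
    simulate_genotypes,
    simulate_phenotypes,
)

__all__ = [
    "qst_fst_single_run",
    "type_i_error",
    "qst_recovery_grid",
    "fst_recovery",
    "selection_detection",
    "effective_df",
]

CHAMBER_PAIR = ("ALP1", "BOR4")
CHAMBER_FULL = ("ALP1", "ALP4", "BOR1", "BOR4")


def qst_fst_single_run(
    seed: int,
    n_pop: int = 11,
    n_ind: int = 25,
    chambers: tuple[str, ...] = CHAMBER_FULL,
    fst_target: float = 0.05,
    sigma_p2: float | None = None,
    sigma_a2: float = 0.3,
    sigma_e2: float = 0.6,
    null_reps: int = 2000,
    qst_variant: str = "textbook",
) -> dict | None:
    """One simulate-estimate-test cycle of the Q_ST-F_ST machinery.

    ``sigma_p2=None`` draws the between-population variance at its neutral
    expectation given the (dosage-masked) differentiation of the simulated
    genotypes, so repeated runs characterize the test's type-I error.  The
    null's additive-variance df is the effective df implied by the REML
    standard error (falling back to genotypes - populations), so that the
    uncertainty of the four-locus kinship-based estimate propagates into
    the neutral distribution.  Returns None when Q_ST is NA.
    """
    g, tg = simulate_genotypes(n_pop=n_pop, n_ind=n_ind, fst_target=fst_target, seed=seed)
    kin = loiselle_kinship(g)
    f_mask = fst_truth(tg)
    s2p = neutral_sigma_p2(f_mask, sigma_a2) if sigma_p2 is None else sigma_p2
    traits, tt = simulate_phenotypes(
        g, {"t": (s2p, sigma_a2, sigma_e2)}, chambers=chambers, seed=seed + 1, kinship=kin
    )
    d = traits.data
    pops = d["individual_id"].map(dict(zip(g.individuals, g.populations))).to_numpy()
    try:
        fit = fit_animal_model(
            d["t"].to_numpy(float), d["chamber_id"].to_numpy(), pops,
            d["individual_id"].to_numpy(), kin,
        )
    except NonConvergenceError:
        return None
    fhat = fst_global(g)
    q = qst(fit, variant=qst_variant)
    if q.is_na or not np.isfinite(fhat.value) or fhat.value <= 0:
        return None
    sa = fit.components["sigma_a2"]
    df_a = effective_df(sa, fit.se["sigma_a2"]) or (n_pop * n_ind - n_pop)
    df_b = combined_df_b(fit.components["sigma_p2"], fit.se["sigma_p2"], n_pop - 1)
    null = simulate_neutral_null(
        fhat.value, max(sa, 1e-12), n_pop=n_pop, n_loci=len(g.loci),
        df_a=df_a, reps=null_reps, seed=seed + 2, qst_variant=qst_variant,
        df_b=df_b,
    )
    test = qst_fst_test(q, fhat, null)
    return {
        "p": test.p_value,
        "qst": q.value,
        "fst": fhat.value,
        "fst_truth": f_mask,
        "sigma_p2_true": s2p,
        "components": dict(fit.components),
        "true_qst": tt.true_qst["t"],
    }


def type_i_error(
    n_runs: int = 500, seed: int = 0, alpha: float = 0.05, **run_kwargs
) -> dict:
    """Rejection rate of the Q_ST-F_ST test under neutral simulation."""
    ps = []
    n_na = 0
    for i in range(n_runs):
        out = qst_fst_single_run(seed + 101 * i, **run_kwargs)
        if out is None:
            n_na += 1
        else:
            ps.append(out["p"])
    ps = np.asarray(ps)
    return {
        "rate": float((ps < alpha).mean()),
        "alpha": alpha,
        "n_runs": len(ps),
        "n_na": n_na,
        "mean_p": float(ps.mean()),
        "p_values": ps,
    }


def qst_recovery_grid(
    sigma_p2_grid=(0.05, 0.15, 0.45),
    sigma_a2_grid=(0.15, 0.3, 0.6),
    n_reps: int = 50,
    seed: int = 0,
    n_pop: int = 11,
    n_ind: int = 15,
    chambers: tuple[str, ...] = CHAMBER_FULL,
    sigma_e2: float = 0.6,
    qst_variant: str = "printed",
) -> list[dict]:
    """Median Q_ST estimate against truth over a (s2_p, s2_a) grid."""
    cells = []
    cell_idx = 0
    for s2p in sigma_p2_grid:
        for s2a in sigma_a2_grid:
            ests = []
            for r in range(n_reps):
                run_seed = seed + 977 * cell_idx + 13 * r
                g, _ = simulate_genotypes(
                    n_pop=n_pop, n_ind=n_ind, fst_target=0.05, seed=run_seed
                )
                kin = loiselle_kinship(g)
                traits, tt = simulate_phenotypes(
                    g, {"t": (s2p, s2a, sigma_e2)}, chambers=chambers,
                    seed=run_seed + 1, kinship=kin,
                )
                d = traits.data
                pops = d["individual_id"].map(
                    dict(zip(g.individuals, g.populations))
                ).to_numpy()
                try:
                    fit = fit_animal_model(
                        d["t"].to_numpy(float), d["chamber_id"].to_numpy(), pops,
                        d["individual_id"].to_numpy(), kin,
                    )
                except NonConvergenceError:
                    continue
                q = qst(fit, variant=qst_variant)
                if not q.is_na:
                    ests.append(q.value)
            truth = s2p / (s2p + s2a) if qst_variant == "printed" else s2p / (s2p + 2 * s2a)
            cells.append(
                {
                    "sigma_p2": s2p,
                    "sigma_a2": s2a,
                    "true_qst": truth,
                    "median_qst": float(np.median(ests)),
                    "n_ok": len(ests),
                }
            )
            cell_idx += 1
    return cells


def fst_recovery(
    targets=(0.01, 0.05, 0.2), n_reps: int = 50, seed: int = 0,
    n_pop: int = 12, n_ind: int = 25,
) -> list[dict]:
    """Mean F_ST estimate vs the exact dosage-masked truth per target."""
    out = []
    for k, target in enumerate(targets):
        diffs = []
        ests = []
        truths = []
        for r in range(n_reps):
            g, tg = simulate_genotypes(
                n_pop=n_pop, n_ind=n_ind, fst_target=target, seed=seed + 499 * k + r
            )
            est = fst_global(g).value
            tru = fst_truth(tg)
            ests.append(est)
            truths.append(tru)
            diffs.append(est - tru)
        diffs = np.asarray(diffs)
        out.append(
            {
                "target": target,
                "mean_est": float(np.mean(ests)),
                "mean_truth": float(np.mean(truths)),
                "mean_diff": float(diffs.mean()),
                "diff_se": float(diffs.std(ddof=1) / np.sqrt(len(diffs))),
                "n": len(diffs),
            }
        )
    return out


def selection_detection(
    n_runs: int = 20,
    seed: int = 0,
    n_pop: int = 11,
    n_ind: int = 15,
    chambers: tuple[str, ...] = CHAMBER_PAIR,
    n_traits: int = 6,
    n_selected: int = 2,
    selection_factor: float = 25.0,
    fst_target: float = 0.05,
    sigma_a2: float = 0.3,
    sigma_e2: float = 0.6,
    alpha: float = 0.01,
    null_reps: int = 2000,
    qst_variant: str = "textbook",
) -> dict:
    """End-to-end detection: traits under divergent selection vs neutral.

    The first ``n_selected`` traits get a between-population variance
    ``selection_factor`` times the neutral expectation; the rest sit at the
    neutral expectation.  Reports per-trait rejection rates at ``alpha``.
    """
    hits = np.zeros(n_traits)
    counts = np.zeros(n_traits)
    for run in range(n_runs):
        run_seed = seed + 7919 * run
        g, tg = simulate_genotypes(
            n_pop=n_pop, n_ind=n_ind, fst_target=fst_target, seed=run_seed
        )
        kin = loiselle_kinship(g)
        f_mask = fst_truth(tg)
        neutral = neutral_sigma_p2(f_mask, sigma_a2)
        spec = {
            f"t{k+1}": (
                selection_factor * neutral if k < n_selected else neutral,
                sigma_a2,
                sigma_e2,
            )
            for k in range(n_traits)
        }
        traits, _ = simulate_phenotypes(
            g, spec, chambers=chambers, seed=run_seed + 1, kinship=kin
        )
        d = traits.data
        pops = d["individual_id"].map(dict(zip(g.individuals, g.populations))).to_numpy()
        fhat = fst_global(g)
        for k, trait in enumerate(spec):
            try:
                fit = fit_animal_model(
                    d[trait].to_numpy(float), d["chamber_id"].to_numpy(), pops,
                    d["individual_id"].to_numpy(), kin,
                )
            except NonConvergenceError:
                continue
            q = qst(fit, variant=qst_variant)
            if q.is_na or fhat.value <= 0:
                continue
            sa = fit.components["sigma_a2"]
            df_a = effective_df(sa, fit.se["sigma_a2"]) or (n_pop * n_ind - n_pop)
            df_b = combined_df_b(
                fit.components["sigma_p2"], fit.se["sigma_p2"], n_pop - 1
            )
            null = simulate_neutral_null(
                fhat.value, max(sa, 1e-12), n_pop=n_pop, n_loci=len(g.loci),
                df_a=df_a, reps=null_reps, seed=run_seed + 2 + k,
                qst_variant=qst_variant, df_b=df_b,
            )
            counts[k] += 1
            if qst_fst_test(q, fhat, null).p_value < alpha:
                hits[k] += 1
    with np.errstate(invalid="ignore"):
        rates = np.where(counts > 0, hits / counts, np.nan)
    return {
        "selected_rates": rates[:n_selected],
        "neutral_rates": rates[n_selected:],
        "counts": counts,
        "alpha": alpha,
        "n_runs": n_runs,
    }
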