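"""Simulated neutral Q_ST - F_ST null distributions and one-sided tests.

Under neutrality the expected between-population additive variance is
2 F_ST / (1 - F_ST) times the within-population additive variance.  Each
null replicate draws

    V_b* = (2 F / (1 - F)) * V_a_hat * chi2(n_pop - 1) / (n_pop - 1)
    V_a* = V_a_hat * chi2(df_a) / df_a
    F*   = F_hat * chi2((n_pop - 1) n_loci) / ((n_pop - 1) n_loci)

(the last being the Lewontin-Krakauer sampling distribution of a multilocus
F_ST), forms Q_ST* from (V_b*, V_a*) under the configured variant, and
stores Q_ST* - F*.  The observed difference is then ranked in this null
with one-sided, add-one-smoothed p-values (divergent-selection
alternative).  Swapping R_ST for F_ST only changes the baseline inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popgen import DifferentiationResult
from .quantgen import QstEstimate

__all__ = [
    "NeutralNull",
    "QstFstTest",
    "simulate_neutral_null",
    "qst_fst_test",
    "effective_df",
    "combined_df_b",
]

DEFAULT_REPS = 20_000


def effective_df(estimate: float, se: float) -> int:
    """Satterthwaite-style effective chi-square df of a variance estimate."""
    if not np.isfinite(se) or se <= 0:
        return 0
    return max(int(round(2.0 * (estimate / se) ** 2)), 1)


def combined_df_b(sigma_p2: float, se_p: float, drift_df: float) -> float:
    """Effective df of the between-population variance under the null.

    The sampled V_b* must reflect drift sampling (chi-square, n_pop - 1 df)
    *and* the REML estimation noise of sigma_p2; matching the combined
    variance of a scaled chi-square gives
    k_eff = 2 s^4 / (2 s^4 / k_drift + SE^2), capped at the drift df.
    """
    if not np.isfinite(se_p) or se_p <= 0 or sigma_p2 <= 0:
        return float(drift_df)
    var_drift = 2.0 * sigma_p2**2 / drift_df
    k = 2.0 * sigma_p2**2 / (var_drift + se_p**2)
    return float(np.clip(k, 1.0, drift_df))


@dataclass
class NeutralNull:
    """Replicate vector of neutral (Q_ST* - F_ST*) with its inputs."""

    diffs: np.ndarray
    fst_hat: float
    va_hat: float
    n_pop: int
    n_loci: int
    df_a: int
    reps: int
    seed: int
    qst_variant: str
    df_b: float | None = None
    qst_sim: np.ndarray = field(repr=False, default=None)
    fst_sim: np.ndarray = field(repr=False, default=None)


def simulate_neutral_null(
    fst_hat: float,
    va_hat: float,
    n_pop: int,
    n_loci: int,
    df_a: int,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    qst_variant: str = "printed",
    df_b: float | None = None,
) -> NeutralNull:
    if not (0 < fst_hat < 1):
        raise ValueError(
            "fst_hat must lie in (0, 1); a zero estimate makes the null "
            "degenerate — apply a small documented floor before calling"
        )
    if va_hat <= 0:
        raise ValueError("va_hat must be positive")
    if n_pop < 2 or reps < 1 or df_a < 1:
        raise ValueError("need n_pop >= 2, reps >= 1, df_a >= 1")
    if qst_variant not in ("printed", "textbook"):
        raise ValueError(f"unknown Q_ST variant {qst_variant!r}")
    rng = np.random.default_rng(seed)
    # df_b defaults to the drift df; callers may pass a smaller effective df
    # when the between-population variance estimate carries extra
    # estimation noise beyond drift sampling (see experiments module)
    k_b = float(df_b) if df_b is not None else n_pop - 1
    if k_b <= 0:
        raise ValueError("df_b must be positive")
    k_f = (n_pop - 1) * n_loci
    vb = (2 * fst_hat / (1 - fst_hat)) * va_hat * rng.chisquare(k_b, reps) / k_b
    va = va_hat * rng.chisquare(df_a, reps) / df_a
    fst = fst_hat * rng.chisquare(k_f, reps) / k_f
    w = 1.0 if qst_variant == "printed" else 2.0
    qst_sim = vb / (vb + w * va)
    return NeutralNull(
        diffs=qst_sim - fst,
        fst_hat=fst_hat,
        va_hat=va_hat,
        n_pop=n_pop,
        n_loci=n_loci,
        df_a=df_a,
        reps=reps,
        seed=seed,
        qst_variant=qst_variant,
        df_b=df_b,
        qst_sim=qst_sim,
        fst_sim=fst,
    )


@dataclass
class QstFstTest:
    """One-sided test of observed Q_ST - F_ST against a simulated null."""

    observed_diff: float
    p_value: float
    quantile: float
    index: str  # baseline index name, e.g. "F_ST" or "R_ST"
    is_na: bool = False


def qst_fst_test(
    observed: QstEstimate, baseline: DifferentiationResult, null: NeutralNull
) -> QstFstTest:
    """p = (1 + #{null >= observed diff}) / (reps + 1), one-sided."""
    if observed.is_na or not np.isfinite(observed.value) or not np.isfinite(baseline.value):
        return QstFstTest(np.nan, np.nan, np.nan, baseline.index, is_na=True)
    diff = observed.value - baseline.value
    n_ge = int(np.sum(null.diffs >= diff))
    p = (1 + n_ge) / (null.reps + 1)
    quantile = float(np.mean(null.diffs < diff))
    return QstFstTest(float(diff), float(p), quantile, baseline.index)
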