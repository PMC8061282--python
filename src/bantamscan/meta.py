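"""Fixed-effects inverse-variance meta-analysis with heterogeneity testing.

Per-study effects are combined with weights w_i = 1 / se_i^2 (the classical
scheme): beta_hat = sum(w b) / sum(w), se_hat = 1 / sqrt(sum(w)), z =
beta_hat / se_hat, two-sided normal p. Before combining, each study can be
genomic-control corrected: when its inflation factor exceeds 1, standard
errors are inflated by sqrt(lambda_GC), i.e. every chi-square is divided by
lambda_GC. Between-study heterogeneity is Cochran's Q = sum w (b - beta_hat)^2
against chi-square with k-1 df, with I^2 = max(0, (Q - (k-1)) / Q) and a
per-study effect-direction string ("+", "-", "?").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import GWAS_THRESHOLD

__all__ = [
    "combine_fixed_effects",
    "genomic_control_correct",
    "heterogeneity",
    "run_meta",
]

log = logging.getLogger(__name__)

_KEY = ["chrom", "pos", "ref", "alt"]


def combine_fixed_effects(
    betas: np.ndarray, ses: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-variance combination along axis 0 (studies).

    ``betas``/``ses`` are (k, m); NaN or non-positive se marks a study as
    missing for that variant. Returns (beta_hat, se_hat, z, p, k_used);
    variants with no valid study are NaN.
    """
    b = np.atleast_2d(np.asarray(betas, dtype=float))
    s = np.atleast_2d(np.asarray(ses, dtype=float))
    valid = np.isfinite(b) & np.isfinite(s) & (s > 0)
    w = np.where(valid, 1.0 / np.where(valid, s, 1.0) ** 2, 0.0)
    wsum = w.sum(axis=0)
    k_used = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_hat = (w * np.where(valid, b, 0.0)).sum(axis=0) / wsum
        se_hat = 1.0 / np.sqrt(wsum)
        z = beta_hat / se_hat
        # keep p in (0, 1]: huge |z| underflows the normal tail
        p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)
    none = k_used == 0
    beta_hat[none] = se_hat[none] = z[none] = p[none] = np.nan
    return beta_hat, se_hat, z, p, k_used


def genomic_control_correct(
    betas: np.ndarray, ses: np.ndarray, lambda_gc: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-study genomic control: inflate se by sqrt(lambda) when lambda > 1.

    Leaves effects (and their signs) untouched; lambda <= 1 is a no-op.
    """
    if lambda_gc <= 0:
        raise ValueError("lambda_GC must be positive")
    if lambda_gc <= 1.0:
        return np.asarray(betas, float), np.asarray(ses, float)
    return np.asarray(betas, float), np.asarray(ses, float) * np.sqrt(lambda_gc)


def heterogeneity(
    betas: np.ndarray, ses: np.ndarray, beta_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cochran's Q, its p-value, I^2 and the direction string per variant.

    Q is undefined (NaN) for variants contributed by a single study.
    """
    b = np.atleast_2d(np.asarray(betas, dtype=float))
    s = np.atleast_2d(np.asarray(ses, dtype=float))
    bh = np.asarray(beta_hat, dtype=float)
    valid = np.isfinite(b) & np.isfinite(s) & (s > 0)
    w = np.where(valid, 1.0 / np.where(valid, s, 1.0) ** 2, 0.0)
    Q = (w * np.where(valid, (b - bh[None, :]) ** 2, 0.0)).sum(axis=0)
    k = valid.sum(axis=0)
    df = k - 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p_het = stats.chi2.sf(Q, df)
        i2 = np.clip((Q - df) / Q, 0.0, 1.0)
    single = k <= 1
    Q = np.where(single, np.nan, Q)
    p_het = np.where(single, np.nan, p_het)
    i2 = np.where(single | (Q == 0), np.where(single, np.nan, 0.0), i2)
    direction = np.empty(b.shape[1], dtype=object)
    signs = np.where(~valid, None, np.where(b >= 0, "+", "-"))
    for j in range(b.shape[1]):
        direction[j] = "".join(signs[i, j] or "?" for i in range(b.shape[0]))
    return Q, df, p_het, i2, direction


def _align_to_first(ref_df: pd.DataFrame, df: pd.DataFrame) -> pd.DataFrame:
    """Align a study's alleles to the first study's (ref, alt) orientation.

    Swapped ref/alt flips the effect sign; anything else is dropped and
    logged.
    """
    merged = df.merge(
        ref_df[_KEY].rename(columns={"ref": "ref0", "alt": "alt0"}),
        left_on=["chrom", "pos"],
        right_on=["chrom", "pos"],
        how="inner",
    )
    same = (merged["ref"] == merged["ref0"]) & (merged["alt"] == merged["alt0"])
    flipped = (merged["ref"] == merged["alt0"]) & (merged["alt"] == merged["ref0"])
    n_drop = int((~same & ~flipped).sum())
    if n_drop:
        log.warning("meta-analysis: %d variants dropped (allele mismatch)", n_drop)
    out = merged[same | flipped].copy()
    flip = flipped[same | flipped]
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, ["ref", "alt"]] = out.loc[flip, ["ref0", "alt0"]].to_numpy()
    return out.drop(columns=["ref0", "alt0"])


def run_meta(
    scans: list[pd.DataFrame],
    lambdas: list[float] | None = None,
    gc_correct: bool = True,
    threshold: float = GWAS_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Combine per-group scans; returns the meta table and a summary dict.

    Studies are matched on (chrom, pos) with allele alignment to the first
    study. Each study is GC-corrected (when requested) before combining.
    The summary reports the significant count at the threshold and the
    fraction of significant multi-study variants with p_het < 0.05 — the
    heterogeneity fraction.
    """
    if not scans:
        raise ValueError("no studies to combine")
    from .gwas import genomic_lambda  # local import to avoid cycle at module load

    aligned = [scans[0]]
    for df in scans[1:]:
        aligned.append(_align_to_first(scans[0], df))

    if lambdas is None:
        lambdas = [
            genomic_lambda(df["p"].dropna().to_numpy()) if df["p"].notna().any() else 1.0
            for df in aligned
        ]

    frames = []
    for i, df in enumerate(aligned):
        sub = df[_KEY + ["beta", "se"]].copy()
        if gc_correct:
            sub["beta"], sub["se"] = genomic_control_correct(
                sub["beta"].to_numpy(), sub["se"].to_numpy(), lambdas[i]
            )
        sub = sub.rename(columns={"beta": f"beta_{i}", "se": f"se_{i}"})
        frames.append(sub)
    table = frames[0]
    for sub in frames[1:]:
        table = table.merge(sub, on=_KEY, how="outer")
    table = table.sort_values(["chrom", "pos"]).reset_index(drop=True)

    k = len(aligned)
    B = table[[f"beta_{i}" for i in range(k)]].to_numpy().T
    S = table[[f"se_{i}" for i in range(k)]].to_numpy().T
    beta_hat, se_hat, z, p, k_used = combine_fixed_effects(B, S)
    Q, df_, p_het, i2, direction = heterogeneity(B, S, beta_hat)

    out = table[_KEY].copy()
    out["beta"] = beta_hat
    out["se"] = se_hat
    out["z"] = z
    out["p"] = p
    out["k"] = k_used
    out["Q"] = Q
    out["df"] = df_
    out["p_het"] = p_het
    out["i2"] = i2
    out["direction"] = direction

    sig = out["p"].notna() & (out["p"] <= threshold)
    multi = sig & (out["k"] >= 2)
    n_multi = int(multi.sum())
    het_frac = (
        float((out.loc[multi, "p_het"] < 0.05).sum()) / n_multi if n_multi else np.nan
    )
    summary = {
        "n_variants": int(len(out)),
        "n_significant": int(sig.sum()),
        "threshold": threshold,
        "lambdas": list(map(float, lambdas)),
        "het_fraction_significant": het_frac,
    }
    return out, summary
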