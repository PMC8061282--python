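"""Case/control association with a univariate linear mixed model.

The phenotype (0 = normal, 1 = bantam) is treated as quantitative and the
model is y = W alpha + x beta + u + e with u ~ N(0, sigma_g^2 K) for an IBS
relatedness matrix K and e ~ N(0, sigma_e^2 I). Writing lambda_vr =
sigma_g^2 / sigma_e^2 and eigendecomposing K = U S U' once, rotation by U'
diagonalizes the covariance, so REML over lambda_vr is a one-dimensional
optimization (grid + Brent refinement) and each variant is scored by
generalized least squares in the rotated space. The default (EMMAX-style)
mode reuses the null-model lambda_vr for every variant; the "exact" mode
re-optimizes it per variant. Significance is the Wald statistic
(beta / se)^2 against chi-square with 1 df.

Residual stratification is gauged by the genomic-control inflation factor:
the median observed association chi-square over the null median 0.4549.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, GenotypeMatrix
from .relatedness import ibs_matrix

__all__ = [
    "LmmFit",
    "ScanSummary",
    "fit_null",
    "score_variants",
    "genomic_lambda",
    "run_group_scan",
    "GWAS_THRESHOLD",
]

GWAS_THRESHOLD = 5e-8
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...

ASSOC_COLUMNS = [
    "chrom", "pos", "ref", "alt", "af_case", "af_ctrl", "n",
    "beta", "se", "p", "stat", "note",
]


@dataclass
class LmmFit:
    """Null-model REML fit, cached in rotated coordinates."""

    lambda_vr: float
    reml_loglik: float
    eigenvalues: np.ndarray
    U: np.ndarray
    y_rot: np.ndarray
    W_rot: np.ndarray
    y: np.ndarray
    W: np.ndarray


@dataclass
class ScanSummary:
    lambda_gc: float
    n_significant: int
    threshold: float = GWAS_THRESHOLD
    n_variants: int = 0
    n_skipped: int = 0


def _reml_neg_loglik(log_lam: float, S: np.ndarray, y_rot: np.ndarray, W_rot: np.ndarray) -> float:
    lam = np.exp(log_lam)
    d = lam * S + 1.0
    wi = 1.0 / d
    n, c = W_rot.shape
    Wd = W_rot * wi[:, None]
    A = W_rot.T @ Wd
    beta = np.linalg.solve(A, Wd.T @ y_rot)
    resid = y_rot - W_rot @ beta
    rss = float(resid @ (resid * wi))
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0 or rss <= 0:
        return np.inf
    return 0.5 * (np.sum(np.log(d)) + logdet_A + (n - c) * np.log(rss))


def fit_null(
    y: np.ndarray,
    K: np.ndarray,
    W: np.ndarray | None = None,
    lambda_bounds: tuple[float, float] = (1e-5, 1e5),
    n_grid: int = 61,
) -> LmmFit:
    """REML fit of the variance ratio on [1e-5, 1e5]; ties go to smaller values.

    K is symmetrized and its eigenvalues clamped at zero (with a warning when
    clamping is material). A constant phenotype is rejected.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype; nothing to fit")
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship dimensions do not match phenotype")
    K = 0.5 * (K + K.T)
    S, U = np.linalg.eigh(K)
    if S.min() < -1e-8 * max(1.0, S.max()):
        warnings.warn("kinship not PSD; clamping negative eigenvalues at 0")
    S = np.clip(S, 0.0, None)
    if W is None:
        W = np.ones((n, 1))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != n:
        W = W.T
    if not np.any(np.all(W == W[0], axis=0) & (W[0] != 0)):
        W = np.column_stack([np.ones(n), W])  # always include an intercept

    y_rot = U.T @ y
    W_rot = U.T @ W
    lo, hi = np.log(lambda_bounds[0]), np.log(lambda_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([_reml_neg_loglik(g, S, y_rot, W_rot) for g in grid])
    best = int(np.argmin(vals))  # first minimum -> smaller lambda on ties
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    if a == b:
        log_lam = grid[best]
    else:
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(a, b), args=(S, y_rot, W_rot), method="bounded"
        )
        log_lam = float(res.x)
        if _reml_neg_loglik(log_lam, S, y_rot, W_rot) > vals[best]:
            log_lam = grid[best]
    lam = float(np.exp(log_lam))
    return LmmFit(
        lambda_vr=lam,
        reml_loglik=-_reml_neg_loglik(log_lam, S, y_rot, W_rot),
        eigenvalues=S,
        U=U,
        y_rot=y_rot,
        W_rot=W_rot,
        y=y,
        W=W,
    )


def _gls_scan(
    fit: LmmFit, X_rot: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized GLS of y on [W, x] per variant at a fixed variance ratio.

    Residualizes x and y against W under the rotated weights (Frisch-Waugh),
    then scores each variant by the univariate weighted regression.
    """
    d = lam * fit.eigenvalues + 1.0
    sw = 1.0 / np.sqrt(d)
    Ww = fit.W_rot * sw[:, None]
    yw = fit.y_rot * sw
    Xw = X_rot * sw[:, None]
    Q, _ = np.linalg.qr(Ww)
    y_t = yw - Q @ (Q.T @ yw)
    X_t = Xw - Q @ (Q.T @ Xw)
    xx = np.einsum("ij,ij->j", X_t, X_t)
    xy = X_t.T @ y_t
    n, c = fit.W_rot.shape
    dof = n - c - 1
    yy = float(y_t @ y_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx
        # floor the residual sum of squares: a binary trait fit as quantitative
        # can be separated perfectly, which would give se = 0 and infinite
        # weights downstream
        rss = np.maximum(yy - beta * xy, 1e-10 * yy)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / xx)
        chi2 = (beta / se) ** 2
        # keep p in (0, 1]: underflowing Wald statistics clamp to the
        # smallest positive float; the chi2 column preserves the ordering
        p = np.maximum(stats.chi2.sf(chi2, 1), 5e-324)
    bad = ~np.isfinite(se) | (xx <= 0) | ~np.isfinite(beta)
    beta[bad], se[bad], p[bad], chi2[bad] = np.nan, np.nan, np.nan, np.nan
    return beta, se, p, chi2


def score_variants(
    fit: LmmFit, X: np.ndarray, mode: str = "null"
) -> pd.DataFrame:
    """Wald association statistics for the rows of ``X`` (variants x samples).

    Missing dosages are imputed to the per-variant mean. Monomorphic
    variants are emitted as NA with a reason. ``mode='exact'`` re-optimizes
    the variance ratio per variant; the default reuses the null fit's.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != fit.y.size:
        raise ValueError("variant vector length does not match phenotype")
    miss = (X == MISSING) | ~np.isfinite(X)
    all_missing = miss.all(axis=1)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=1)
    col_mean = np.where(all_missing, 0.0, col_mean)
    Xi = np.where(miss, col_mean[:, None], X)
    mono = all_missing | (Xi.max(axis=1) == Xi.min(axis=1))

    X_rot = fit.U.T @ Xi.T  # samples x variants, rotated

    if mode == "null":
        beta, se, p, chi2 = _gls_scan(fit, X_rot, fit.lambda_vr)
    elif mode == "exact":
        m = X.shape[0]
        beta, se, p, chi2 = (np.full(m, np.nan) for _ in range(4))
        K = (fit.U * fit.eigenvalues) @ fit.U.T
        extra = fit.W[:, 1:] if fit.W.shape[1] > 1 else None
        for i in range(m):
            if mono[i]:
                continue
            cov = Xi[i] if extra is None else np.column_stack([extra, Xi[i]])
            lam_i = fit_null(fit.y, K, cov).lambda_vr
            b, s, pv, c2 = _gls_scan(fit, X_rot[:, [i]], lam_i)
            beta[i], se[i], p[i], chi2[i] = b[0], s[0], pv[0], c2[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)
    p = np.where(mono, np.nan, p)
    chi2 = np.where(mono, np.nan, chi2)
    note = np.where(mono, "monomorphic", "")
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "stat": chi2, "note": note})


def genomic_lambda(pvals: np.ndarray) -> float:
    """Genomic-control inflation factor from a vector of p-values."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_MEDIAN)


def run_group_scan(
    gm: GenotypeMatrix,
    samples: pd.DataFrame,
    group_id: int | None,
    K: np.ndarray | None = None,
    mode: str = "null",
    threshold: float = GWAS_THRESHOLD,
    kinship_sites: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
) -> tuple[pd.DataFrame, ScanSummary]:
    """Scan all variants in one group (or pooled, with ``group_id=None``).

    Cases are the bantam-sized samples of the group (true-bantam sources and
    neo-bantams), controls the normal-sized counterparts. K defaults to the
    IBS similarity matrix of the scanned samples; pass ``K=np.eye(n)`` to
    disable the random effect (reduces to ordinary least squares).
    """
    sub = samples if group_id is None else samples[samples["group"] == group_id]
    ids = list(sub["sample_id"])
    if not ids:
        raise ValueError(f"no samples in group {group_id}")
    y = (sub["size_class"].to_numpy() == "bantam").astype(float)
    if y.min() == y.max():
        raise ValueError(f"group {group_id}: need both cases and controls")
    g = gm.take_samples(ids)
    if K is None:
        sim, _ = ibs_matrix(g, level="sample", site_subset=kinship_sites)
        K = sim
    fit = fit_null(y, K, covariates)
    stats_df = score_variants(fit, g.dosages.astype(float), mode=mode)

    cases = y == 1
    d = g.dosages.astype(float)
    m = g.dosages != MISSING
    with np.errstate(invalid="ignore"):
        af_case = np.where(m[:, cases], d[:, cases], 0).sum(axis=1) / np.maximum(
            2 * m[:, cases].sum(axis=1), 1
        )
        af_ctrl = np.where(m[:, ~cases], d[:, ~cases], 0).sum(axis=1) / np.maximum(
            2 * m[:, ~cases].sum(axis=1), 1
        )
    out = g.sites[["chrom", "pos", "ref", "alt"]].copy()
    out["af_case"] = af_case
    out["af_ctrl"] = af_ctrl
    out["n"] = m.sum(axis=1)
    out["beta"] = stats_df["beta"].to_numpy()
    out["se"] = stats_df["se"].to_numpy()
    out["p"] = stats_df["p"].to_numpy()
    out["stat"] = stats_df["stat"].to_numpy()
    out["note"] = stats_df["note"].to_numpy()
    finite = out["p"].notna()
    summary = ScanSummary(
        lambda_gc=genomic_lambda(out.loc[finite, "p"].to_numpy()),
        n_significant=int((out.loc[finite, "p"] <= threshold).sum()),
        threshold=threshold,
        n_variants=int(finite.sum()),
        n_skipped=int((~finite).sum()),
    )
    return out, summary
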