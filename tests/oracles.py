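"""Independent oracle implementations used only by the tests.

These are deliberately written as plain scalar transcriptions (or thin
statsmodels calls), separate from the package's vectorized code paths, so
that agreement between the two routes is a meaningful check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


# ------------------------------------------------- Weir-Cockerham, two pops


def wc_abc_scalar(g1, g2):
    """Per-site W&C (1984) variance components, explicit scalar arithmetic.

    ``g1``/``g2`` are sequences of diploid dosages (0/1/2) with None/-1 for
    missing. Returns (a, b, c) or None when a population has <2 genotypes
    or the site is monomorphic overall.
    """
    def summarize(g):
        vals = [x for x in g if x is not None and x >= 0]
        n = len(vals)
        if n < 2:
            return None
        p = sum(vals) / (2.0 * n)
        h = sum(1 for x in vals if x == 1) / n
        return n, p, h

    s1, s2 = summarize(g1), summarize(g2)
    if s1 is None or s2 is None:
        return None
    n1, p1, h1 = s1
    n2, p2, h2 = s2
    r = 2.0
    nbar = (n1 + n2) / r
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar == 0.0 or pbar == 1.0:
        return None
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    s2v = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2v - 1.0 / (nbar - 1.0) * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2v - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - (r - 1.0) / r * s2v
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst_window_scalar(geno1_rows, geno2_rows) -> float:
    """Ratio-of-sums window estimator from the scalar per-site components."""
    num = den = 0.0
    for g1, g2 in zip(geno1_rows, geno2_rows):
        abc = wc_abc_scalar(g1, g2)
        if abc is None:
            continue
        a, b, c = abc
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


# ------------------------------------------------------------- OLS Wald test


def ols_wald(y, x):
    """OLS of y on [1, x]; Wald chi-square p for the slope (via statsmodels)."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    beta = res.params[1]
    se = res.bse[1]
    chi2 = (beta / se) ** 2
    return beta, se, float(stats.chi2.sf(chi2, 1))


# -------------------------------------------------------- meta-analysis WLS


def meta_wls(betas, ses):
    """Fixed-effects combination as an intercept-only WLS fit.

    Returns (beta_hat, se_hat, Q): the weighted mean, its standard error
    under fixed weights, and the weighted residual sum of squares.
    """
    import statsmodels.api as sm

    b = np.asarray(betas, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    res = sm.WLS(b, np.ones_like(b), weights=w).fit()
    beta_hat = float(res.params[0])
    se_hat = float(1.0 / np.sqrt(w.sum()))
    Q = float(np.sum(w * (b - beta_hat) ** 2))
    return beta_hat, se_hat, Q


# ------------------------------------------- unrooted topology enumeration


def enumerate_unrooted_topologies(n_leaves: int):
    """All unrooted binary topologies on leaves L0..L{n-1} as skbio TreeNodes.

    Built by sequential insertion of each new leaf on every edge; yields
    3, 15, 105 trees for 4, 5, 6 leaves.
    """
    from skbio import TreeNode

    base = TreeNode(
        children=[TreeNode(name="L0"), TreeNode(name="L1"), TreeNode(name="L2")]
    )
    trees = [base]
    for leaf_i in range(3, n_leaves):
        nxt = []
        for t in trees:
            edges = [n for n in t.traverse(include_self=False)]
            for e_idx in range(len(edges)):
                t2 = t.copy()
                target = [n for n in t2.traverse(include_self=False)][e_idx]
                parent = target.parent
                parent.remove(target)
                mid = TreeNode(children=[target, TreeNode(name=f"L{leaf_i}")])
                parent.append(mid)
                nxt.append(t2)
        trees = nxt
    return trees


def assign_random_lengths(tree, rng, lo=0.1, hi=1.0):
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(lo, hi))
    tree.length = None
    return tree


def bipartitions(tree) -> set:
    """Non-trivial leaf bipartitions (as frozensets of the smaller side names)."""
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts
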