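"""Population structure: IBS similarity, PCA and neighbor-joining trees.

IBS (identity by state) is computed in dosage space: for a sample pair the
per-locus similarity is (2 - |g_i - g_j|) / 2 averaged over loci non-missing
in both (pairwise-complete). At haplotype level it is simply the fraction of
identical alleles. 1 - IBS is the distance fed to the NJ tree.

The NJ implementation is the classical Saitou-Nei agglomeration with
deterministic lexicographic tie-breaking on the Q-matrix and negative branch
lengths clamped to zero; trees are returned as ``skbio.TreeNode`` with the
standard unrooted trifurcation at the root.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "ibs_matrix",
    "pca",
    "PcaResult",
    "nj_tree",
    "write_newick",
    "read_newick",
]


# ------------------------------------------------------------------------ IBS


def ibs_matrix(
    gm: GenotypeMatrix, level: str = "sample", site_subset: np.ndarray | None = None
) -> tuple[np.ndarray, DistanceMatrix]:
    """IBS similarity and the 1-IBS distance matrix.

    ``level='sample'`` works on dosages; ``level='haplotype'`` needs phased
    input and compares the 2n haplotype columns. Pairs with zero overlapping
    non-missing loci get NaN similarity and are reported via the matrix.
    """
    if level == "sample":
        X = gm.dosages
        labels = list(gm.samples)
    elif level == "haplotype":
        if gm.haplotypes is None:
            raise ValueError("haplotype-level IBS requires phased input")
        X = gm.haplotypes
        labels = gm.haplotype_labels()
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(labels) < 2:
        raise ValueError("need at least two samples/haplotypes")
    if site_subset is not None:
        X = X[np.asarray(site_subset)]

    X = X.astype(np.float64)
    M = X != MISSING
    n = X.shape[1]
    sim = np.ones((n, n))
    denom_scale = 2.0 if level == "sample" else 1.0
    for i in range(n):
        both = M[:, i, None] & M[:, i + 1 :]
        diff = np.abs(X[:, i, None] - X[:, i + 1 :])
        counts = both.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            s = 1.0 - np.where(both, diff, 0.0).sum(axis=0) / (denom_scale * counts)
        s[counts == 0] = np.nan
        sim[i, i + 1 :] = s
        sim[i + 1 :, i] = s
    # self-similarity is 1 whenever at least one locus is observed
    for i in range(n):
        if not M[:, i].any():
            sim[i, i] = np.nan
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        raise ValueError(
            "pairs with zero overlapping loci present; cannot build a complete "
            "distance matrix"
        )
    return sim, DistanceMatrix(dist, ids=labels)


# ------------------------------------------------------------------------ PCA


class PcaResult:
    """PCA coordinates and explained variance, ordered by eigenvalue."""

    def __init__(self, coords: np.ndarray, explained: np.ndarray, samples: list[str]):
        self.coords = coords
        self.explained_variance = explained
        self.samples = samples

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])],
        )
        df.insert(0, "sample_id", self.samples)
        return df


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Genotype PCA with the usual per-variant standardization.

    Dosages are mean-centered and scaled by sqrt(2 p (1 - p)); missing
    genotypes are imputed to the per-variant mean (i.e. zero after
    centering). Eigenvectors of the sample covariance give the coordinates.
    Component signs are arbitrary.
    """
    if n_components > gm.n_samples:
        raise ValueError("more components requested than samples")
    X = gm.dosages.astype(float)
    miss = gm.dosages == MISSING
    p = gm.alt_freq()
    mean = 2.0 * p
    sd = np.sqrt(np.clip(2.0 * p * (1.0 - p), 0.0, None))
    informative = np.isfinite(p) & (sd > 0)
    X = X[informative]
    Xc = (X - mean[informative, None]) / sd[informative, None]
    Xc[miss[informative]] = 0.0
    Z = Xc.T  # samples x variants
    m = Z.shape[1]
    cov = Z @ Z.T / m
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    return PcaResult(coords, vals, list(gm.samples))


# ------------------------------------------------------------------------- NJ


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is chosen scanning the upper
    triangle in lexicographic order; branch lengths use the standard NJ
    formulas with negative values clamped to 0. The returned tree is
    unrooted (trifurcating root) for n >= 3.
    """
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    n = len(nodes)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix has missing entries")

    while n > 3:
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lexicographic argmin over the upper triangle
        iu, ju = np.triu_indices(n, k=1)
        k = int(np.argmin(Q[iu, ju]))
        i, j = int(iu[k]), int(ju[k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        new = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        D2 = np.empty((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[x] for x in keep] + [new]
        D = D2
        n -= 1

    # closed-form star resolution for the last three nodes
    a, b, c = nodes
    la = max(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]), 0.0)
    lb = max(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]), 0.0)
    lc = max(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]), 0.0)
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    return TreeNode(children=[a, b, c])


# ---------------------------------------------------------------------- I/O


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize to Newick with branch lengths; labels needing it are quoted."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            s = _quote(node.name or "")
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                s += _quote(node.name)
        if node.length is not None:
            s += f":{node.length:.10g}"
        return s

    text = render(tree) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_newick(source) -> TreeNode:
    return TreeNode.read(source, convert_underscores=False)
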