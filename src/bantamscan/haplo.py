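"""Lead-variant haplotype blocks, LD profiles and phenotype-aware trees.

The "PhyloGWAS" idea: restrict the data to phenotype-associated variants (or
to the phased haplotypes around a lead variant) and ask whether samples then
cluster by phenotype rather than by overall relatedness — the signature of
shared causal variation across otherwise unrelated populations.

LD is computed from phased haplotype frequencies:
r^2 = (p_AB - p_A p_B)^2 / (p_A (1 - p_A) p_B (1 - p_B)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import MISSING, GenotypeMatrix
from .relatedness import PcaResult, ibs_matrix, nj_tree, pca

__all__ = [
    "HaplotypeBlock",
    "extract_block",
    "ld_r2",
    "ld_profile",
    "block_tree",
    "significant_variant_view",
    "HIGH_LD_R2",
]

#: reporting threshold for "high LD" interval bounds around a lead variant
HIGH_LD_R2 = 0.9


@dataclass
class HaplotypeBlock:
    """Phased haplotypes over a lead-variant-centered region."""

    chrom: str
    start: int
    end: int
    lead_pos: int
    sites: pd.DataFrame
    haplotypes: np.ndarray  # (n_sites, 2 * n_samples)
    labels: list[str]  # sample_hapIndex, optionally annotated
    samples: list[str]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def allele_strings(self) -> list[str]:
        return [
            "".join("." if a == MISSING else str(int(a)) for a in self.haplotypes[:, j])
            for j in range(self.n_haplotypes)
        ]


def extract_block(
    gm: GenotypeMatrix,
    lead_chrom: str,
    lead_pos: int,
    flank_bp: int = 1000,
    samples: pd.DataFrame | None = None,
) -> HaplotypeBlock:
    """All phased sites within lead +- flank, two haplotypes per individual.

    When a sample table is supplied, haplotype labels carry the group and
    size class as suffixes (sample_hap|group|phenotype).
    """
    if not gm.phased or gm.haplotypes is None:
        raise ValueError("haplotype blocks require phased input")
    mask = gm.region_mask(lead_chrom, lead_pos - flank_bp, lead_pos + flank_bp)
    if not ((gm.sites["chrom"] == lead_chrom) & (gm.sites["pos"] == lead_pos)).any():
        raise ValueError(f"lead variant {lead_chrom}:{lead_pos} absent from the data")
    sub = gm.take_sites(mask)
    labels = sub.haplotype_labels()
    if samples is not None:
        meta = samples.set_index("sample_id")
        labels = [
            f"{lab}|g{meta.loc[lab.rsplit('_', 1)[0], 'group']}"
            f"|{meta.loc[lab.rsplit('_', 1)[0], 'size_class']}"
            for lab in labels
        ]
    return HaplotypeBlock(
        chrom=lead_chrom,
        start=lead_pos - flank_bp,
        end=lead_pos + flank_bp,
        lead_pos=lead_pos,
        sites=sub.sites,
        haplotypes=sub.haplotypes,
        labels=labels,
        samples=list(gm.samples),
    )


def ld_r2(hap_marker: np.ndarray, hap_lead: np.ndarray) -> float:
    """r^2 between two sites from phased haplotype alleles (0/1).

    NaN when either site is monomorphic over the jointly non-missing
    haplotypes. Symmetric in its arguments and invariant to allele
    relabeling.
    """
    a = np.asarray(hap_marker)
    b = np.asarray(hap_lead)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if a.size == 0:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_profile(block: HaplotypeBlock) -> pd.DataFrame:
    """r^2 of every marker in the block against the lead variant."""
    lead_row = int(np.flatnonzero(block.sites["pos"].to_numpy() == block.lead_pos)[0])
    lead = block.haplotypes[lead_row]
    return pd.DataFrame(
        {
            "chrom": block.sites["chrom"],
            "pos": block.sites["pos"],
            "r2": [ld_r2(block.haplotypes[i], lead) for i in range(len(block.sites))],
        }
    )


def block_tree(block: HaplotypeBlock) -> TreeNode:
    """NJ tree of the block's haplotypes from 1-IBS distances."""
    if block.n_haplotypes < 3:
        raise ValueError("need at least 3 haplotypes for a tree")
    H = block.haplotypes.astype(np.float64)
    M = H != MISSING
    n = block.n_haplotypes
    dist = np.zeros((n, n))
    for i in range(n):
        both = M[:, i, None] & M[:, i + 1 :]
        diff = (H[:, i, None] != H[:, i + 1 :]) & both
        counts = both.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            d = diff.sum(axis=0) / counts
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    from skbio import DistanceMatrix

    return nj_tree(DistanceMatrix(dist, ids=block.labels))


def significant_variant_view(
    gm: GenotypeMatrix,
    significant: np.ndarray,
    samples: pd.DataFrame | None = None,
    n_components: int = 2,
) -> tuple[PcaResult, TreeNode]:
    """PCA and NJ tree restricted to the significant variant set.

    ``significant`` is a boolean mask or integer index over ``gm`` sites.
    """
    significant = np.asarray(significant)
    if significant.dtype == bool:
        if not significant.any():
            raise ValueError("empty significant set")
    elif significant.size == 0:
        raise ValueError("empty significant set")
    sub = gm.take_sites(significant)
    coords = pca(sub, n_components=min(n_components, sub.n_samples))
    _, dm = ibs_matrix(sub, level="sample")
    if samples is not None:
        meta = samples.set_index("sample_id")
        relabel = {
            sid: f"{sid}|g{meta.loc[sid, 'group']}|{meta.loc[sid, 'size_class']}"
            for sid in sub.samples
        }
        dm = dm.__class__(dm.data, ids=[relabel[s] for s in sub.samples])
    tree = nj_tree(dm)
    return coords, tree
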