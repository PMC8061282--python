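"""Core in-memory containers shared across the pipeline.

``GenotypeMatrix`` holds bi-allelic alt-allele dosages (variants x samples)
plus a site table; when the input was fully phased it additionally carries a
0/1 haplotype matrix with two haplotype columns per sample. The sample
metadata table is a plain pandas DataFrame with the columns
``sample_id, breed, size_class, role, group``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SAMPLE_COLUMNS",
    "read_sample_table",
    "write_sample_table",
]

MISSING: int = -1  # sentinel for a missing dosage / allele

SAMPLE_COLUMNS = ["sample_id", "breed", "size_class", "role", "group"]

#: site-table columns every GenotypeMatrix carries
SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "site_id"]


@dataclass
class GenotypeMatrix:
    """Variants x samples alt-allele dosage matrix with site metadata.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos (1-based), ref, alt, qual,
        site_id (original identifier; multi-allelic splits share a prefix).
    samples : list of sample ids (column order of ``dosages``).
    dosages : int8 array (n_sites, n_samples), values {0, 1, 2, MISSING}.
    depth : optional per-genotype depth, same shape (MISSING when absent).
    phased : True when every genotype in the source was phased.
    haplotypes : optional int8 array (n_sites, 2 * n_samples) of 0/1 alleles;
        haplotype columns are ordered s0_h1, s0_h2, s1_h1, ...
    """

    sites: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray
    depth: np.ndarray | None = None
    phased: bool = False
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage matrix shape does not match sites/samples")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (len(self.sites), 2 * len(self.samples)):
                raise ValueError("haplotype matrix shape mismatch")

    # ------------------------------------------------------------ properties

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def haplotype_labels(self) -> list[str]:
        return [f"{s}_{h}" for s in self.samples for h in (1, 2)]

    # -------------------------------------------------------------- queries

    def alt_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing genotypes (NaN if none)."""
        d = self.dosages.astype(float)
        mask = self.dosages != MISSING
        called = mask.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(mask, d, 0.0).sum(axis=1) / np.where(
                called > 0, 2.0 * called, np.nan
            )

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=1)

    # ------------------------------------------------------------- subsets

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            sites=self.sites.iloc[index],
            dosages=self.dosages[index],
            depth=None if self.depth is None else self.depth[index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
        )

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        hap_idx = [2 * i + h for i in idx for h in (0, 1)]
        return replace(
            self,
            samples=list(sample_ids),
            dosages=self.dosages[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, hap_idx],
        )

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask for sites with 1-based position in [start, end]."""
        return (
            (self.sites["chrom"] == chrom)
            & (self.sites["pos"] >= start)
            & (self.sites["pos"] <= end)
        ).to_numpy()


# ----------------------------------------------------------------- metadata


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": int})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table {path} lacks columns: {sorted(missing)}")
    return df


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
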