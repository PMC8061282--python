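"""Positional variant-to-gene assignment and cross-analysis overlap sets.

A variant is assigned to every gene whose span, extended by a symmetric
flank (default 1 kb, covering promoter-proximal territory), contains it;
variants hitting no extended gene are flagged intergenic. Overlap summaries
compare the significant-variant sets of several analyses (e.g. the per-group
scans and the meta-analysis) and the gene sets they imply — a gene counts as
hit by an analysis when at least one of its significant variants is assigned
to it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "read_gene_models",
    "assign_variants",
    "overlap_sets",
    "OverlapSummary",
]

GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "name", "biotype"]


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Load gene models from GFF3 or BED into a 1-based inclusive table."""
    path = Path(path)
    if path.suffix.lower() in (".bed",):
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        out = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[1].astype(int) + 1,  # BED is 0-based half-open
                "end": df[2].astype(int),
                "strand": df[5] if df.shape[1] > 5 else ".",
                "gene_id": df[3].astype(str) if df.shape[1] > 3 else "",
                "name": df[3].astype(str) if df.shape[1] > 3 else "",
                "biotype": "",
            }
        )
        return out[GENE_COLUMNS]
    # GFF3 via gffutils (coding and noncoding gene features alike)
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="warning"
    )
    rows = []
    for ftype in ("gene", "ncRNA_gene", "pseudogene"):
        for f in db.features_of_type(ftype):
            rows.append(
                (
                    f.seqid,
                    f.start,
                    f.end,
                    f.strand or ".",
                    f.id,
                    (f.attributes.get("Name") or [f.id])[0],
                    (f.attributes.get("biotype") or [""])[0],
                )
            )
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if (genes["start"] > genes["end"]).any():
        raise ValueError(f"{path}: gene with start > end")
    return genes


def assign_variants(
    variants: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 1000
) -> pd.DataFrame:
    """Assign each variant to every gene within [start - flank, end + flank].

    ``variants`` needs chrom/pos (1-based); overlapping genes yield one row
    per gene; unassigned variants get a single row with gene_id NA and
    intergenic=True. Chromosome name mismatch (no shared chromosomes at all)
    is reported explicitly.
    """
    vchroms = set(variants["chrom"].astype(str))
    gchroms = set(genes["chrom"].astype(str))
    if vchroms and gchroms and not (vchroms & gchroms):
        raise ValueError(
            f"no shared chromosome names between variants ({sorted(vchroms)[:3]}...) "
            f"and genes ({sorted(gchroms)[:3]}...)"
        )
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # interval is half-open; +1 to make the 1-based inclusive end interior
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            row.start - flank_bp, row.end + flank_bp + 1, (row.gene_id, row.name)
        )
    out = []
    for v in variants.itertuples(index=False):
        hits = trees.get(str(v.chrom), IntervalTree())[int(v.pos)]
        if hits:
            for h in sorted(hits, key=lambda h: h.data):
                out.append((v.chrom, v.pos, h.data[0], h.data[1], False))
        else:
            out.append((v.chrom, v.pos, pd.NA, pd.NA, True))
    return pd.DataFrame(out, columns=["chrom", "pos", "gene_id", "name", "intergenic"])


class OverlapSummary:
    """Membership matrix + shared/unique counts across named analyses."""

    def __init__(self, sets: dict[str, set]):
        if len(sets) < 1:
            raise ValueError("need at least one analysis")
        self.names = list(sets)
        universe = sorted(set().union(*sets.values()), key=str)
        self.membership = pd.DataFrame(
            {name: [e in sets[name] for e in universe] for name in self.names},
            index=universe,
        )

    def shared_by_at_least(self, k: int) -> set:
        counts = self.membership.sum(axis=1)
        return set(self.membership.index[counts >= k])

    def shared_by_exactly(self, k: int) -> set:
        counts = self.membership.sum(axis=1)
        return set(self.membership.index[counts == k])

    def unique_to(self, name: str) -> set:
        counts = self.membership.sum(axis=1)
        return set(self.membership.index[(counts == 1) & self.membership[name]])

    def counts(self) -> pd.DataFrame:
        rows = [("total", len(self.membership))]
        for k in range(1, len(self.names) + 1):
            rows.append((f"shared_by_exactly_{k}", len(self.shared_by_exactly(k))))
            rows.append((f"shared_by_at_least_{k}", len(self.shared_by_at_least(k))))
        return pd.DataFrame(rows, columns=["set", "count"])


def overlap_sets(named_sets: dict[str, set]) -> OverlapSummary:
    """Shared/unique element sets among >=1 named analyses (variants or genes)."""
    return OverlapSummary({k: set(v) for k, v in named_sets.items()})
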