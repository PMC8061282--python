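"""VCF ingestion and the variant quality-control cascade.

The QC follows the usual whole-genome-resequencing recipe for this kind of
panel: per-genotype depth masking first, then site filters on quality, call
rate (recomputed after masking) and mean depth, and finally a minor-allele-
frequency cut. Multi-allelic records are split into bi-allelic rows, one per
alternate allele, each with its own allele identifier so no information is
lost. Sample sex is inferred from the W/Z sequence-coverage ratio
(chickens: males ZZ, females ZW).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "read_vcf",
    "split_record",
    "apply_qc",
    "infer_sex",
    "write_vcf",
]


@dataclass
class QcThresholds:
    """Site/genotype filter bounds.

    Quality and call rate are strict ('over 10', 'more than 0.8'); depth
    bounds are inclusive. MAF sites are removed only when strictly below
    ``min_maf``.
    """

    min_site_quality: float = 10.0
    min_call_rate: float = 0.8
    site_mean_depth: tuple[float, float] = (3.0, 100.0)
    genotype_depth: tuple[float, float] = (3.0, 100.0)
    min_maf: float = 0.05


@dataclass
class QcReport:
    n_input: int
    n_pass: int
    genotypes_masked: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_sites", self.n_input), ("genotypes_masked", self.genotypes_masked)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("passing_sites", self.n_pass))
        return pd.DataFrame(rows, columns=["metric", "count"])


# ---------------------------------------------------------------------- read


def split_record(
    ref: str, alts: list[str], allele_pairs: np.ndarray
) -> list[tuple[str, np.ndarray]]:
    """Split one (possibly multi-allelic) record into bi-allelic rows.

    ``allele_pairs`` is an (n_samples, 2) int array of allele indices with
    negatives for missing. Returns one ``(alt, dosages)`` per alternate
    allele; in row k, alleles other than alt k count as the reference class.
    A genotype with any missing allele is missing in every output row.
    """
    pairs = np.asarray(allele_pairs)
    missing = (pairs < 0).any(axis=1)
    out = []
    for k, alt in enumerate(alts):
        dos = (pairs == k + 1).sum(axis=1).astype(np.int8)
        dos[missing] = MISSING
        out.append((alt, dos))
    return out


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF 4.x into a GenotypeMatrix.

    Multi-allelic records are split; phase is preserved (and a haplotype
    matrix built) only when every genotype in the file is phased; per-
    genotype DP is captured when present. Malformed records raise with the
    record index and coordinate for context.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_rows, dosage_rows, depth_rows, hap_rows = [], [], [], []
    all_phased = True
    has_depth = False
    for rec_i, rec in enumerate(vcf):
        try:
            gts = np.array(rec.genotypes, dtype=object)
            pairs = np.array([[g[0], g[1]] for g in gts], dtype=np.int64)
            if any(len(g) != 3 for g in gts):
                raise ValueError("mixed ploidy")
            phased_flags = np.array([bool(g[2]) for g in gts])
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(
                f"malformed record #{rec_i + 1} at {rec.CHROM}:{rec.POS}: {exc}"
            ) from exc
        all_phased = all_phased and bool(phased_flags.all())
        try:
            dp = rec.format("DP")
        except KeyError:  # DP absent from the header entirely
            dp = None
        if dp is not None:
            has_depth = True
            dp = np.where(dp < 0, MISSING, dp).astype(np.int32).reshape(-1)
        rec_id = rec.ID or f"{rec.CHROM}_{rec.POS}"
        alts = list(rec.ALT)
        pieces = split_record(rec.REF, alts, pairs)
        for k, (alt, dos) in enumerate(pieces):
            suffix = f"_alt{k + 1}" if len(pieces) > 1 else ""
            site_rows.append(
                (rec.CHROM, rec.POS, rec.REF, alt, rec.QUAL, f"{rec_id}{suffix}")
            )
            dosage_rows.append(dos)
            depth_rows.append(dp if dp is not None else np.full(len(samples), MISSING, np.int32))
            if len(pieces) == 1:
                h = pairs.copy()
                h[(pairs < 0).any(axis=1)] = MISSING
                hap_rows.append(h.reshape(-1).astype(np.int8))
            else:
                # per-alt recoding of phased alleles
                h = (pairs == k + 1).astype(np.int8)
                h[(pairs < 0).any(axis=1)] = MISSING
                hap_rows.append(h.reshape(-1))
    sites = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "ref", "alt", "qual", "site_id"]
    )
    dosages = (
        np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(samples)), np.int8)
    )
    depth = np.vstack(depth_rows) if has_depth else None
    haps = (
        np.vstack(hap_rows).astype(np.int8)
        if all_phased and hap_rows
        else None
    )
    return GenotypeMatrix(
        sites=sites,
        samples=samples,
        dosages=dosages,
        depth=depth,
        phased=all_phased and bool(hap_rows),
        haplotypes=haps,
    )


# ------------------------------------------------------------------------ QC


def apply_qc(
    gm: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC cascade; returns the filtered matrix and a report.

    Order of operations: (1) genotypes with depth outside the genotype-depth
    bounds are masked to missing; (2) sites failing quality, post-masking
    call rate, or mean depth are removed; (3) sites with MAF strictly below
    the threshold are removed. A site that passes pre-masking call rate but
    fails it after masking is attributed to the genotype-depth rule.
    """
    t = thresholds or QcThresholds()
    dosages = gm.dosages.copy()
    haps = None if gm.haplotypes is None else gm.haplotypes.copy()

    n_masked = 0
    if gm.depth is not None:
        lo, hi = t.genotype_depth
        bad = (gm.depth != MISSING) & ((gm.depth < lo) | (gm.depth > hi))
        bad &= dosages != MISSING
        n_masked = int(bad.sum())
        dosages[bad] = MISSING
        if haps is not None:
            haps[np.repeat(bad, 2, axis=1)] = MISSING

    pre_call = (gm.dosages != MISSING).mean(axis=1)
    post_call = (dosages != MISSING).mean(axis=1)

    qual = gm.sites["qual"].to_numpy(dtype=float)
    fail_quality = ~(qual > t.min_site_quality)

    fail_call = ~(post_call > t.min_call_rate)
    fail_call_geno = fail_call & (pre_call > t.min_call_rate)  # masking-induced
    fail_call_raw = fail_call & ~fail_call_geno

    if gm.depth is not None:
        dmask = gm.depth != MISSING
        with np.errstate(invalid="ignore"):
            mean_depth = np.where(dmask, gm.depth, 0).sum(axis=1) / np.maximum(
                dmask.sum(axis=1), 1
            )
        mean_depth[dmask.sum(axis=1) == 0] = np.nan
        lo, hi = t.site_mean_depth
        fail_depth = ~((mean_depth >= lo) & (mean_depth <= hi))
    else:
        fail_depth = np.zeros(gm.n_sites, dtype=bool)

    # MAF on non-missing alleles, after masking
    d = dosages.astype(float)
    called = (dosages != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(dosages != MISSING, d, 0.0).sum(axis=1) / np.maximum(2 * called, 1)
    maf = np.minimum(p, 1 - p)
    fail_maf = maf < t.min_maf

    reason = np.full(gm.n_sites, "", dtype=object)
    for name, mask in [
        ("quality", fail_quality),
        ("call_rate", fail_call_raw),
        ("genotype_depth", fail_call_geno),
        ("mean_depth", fail_depth),
        ("maf", fail_maf),
    ]:
        reason[(reason == "") & mask] = name

    keep = reason == ""
    removed = {
        name: int((reason == name).sum())
        for name in ["quality", "call_rate", "genotype_depth", "mean_depth", "maf"]
    }
    filtered = GenotypeMatrix(
        sites=gm.sites.loc[keep],
        samples=list(gm.samples),
        dosages=dosages[keep],
        depth=None if gm.depth is None else gm.depth[keep],
        phased=gm.phased,
        haplotypes=None if haps is None else haps[keep],
    )
    report = QcReport(
        n_input=gm.n_sites,
        n_pass=int(keep.sum()),
        genotypes_masked=n_masked,
        removed=removed,
    )
    return filtered, report


# ----------------------------------------------------------------------- sex


def infer_sex(
    mean_depth_z: np.ndarray, mean_depth_w: np.ndarray, threshold: float = 0.3
) -> np.ndarray:
    """Classify samples as ZZ male / ZW female from the W/Z coverage ratio.

    A ratio >= ``threshold`` calls a ZW female (females carry one W and one
    Z, so their W coverage approaches their Z coverage; males have ~none).
    """
    z = np.asarray(mean_depth_z, dtype=float)
    w = np.asarray(mean_depth_w, dtype=float)
    if np.any(z <= 0):
        raise ValueError("zero or negative Z coverage; cannot form W/Z ratio")
    return np.where(w / z >= threshold, "ZW_female", "ZZ_male")


# ---------------------------------------------------------------------- write


def write_vcf(gm: GenotypeMatrix, path: str | Path, contig_lengths: dict | None = None) -> None:
    """Serialize a GenotypeMatrix back to VCF (GT and, when present, DP)."""
    contigs = contig_lengths or {
        c: int(g["pos"].max()) + 1 for c, g in gm.sites.groupby("chrom", sort=False)
    }
    fmt = "GT:DP" if gm.depth is not None else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=bantamscan-qc\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        sep = "|" if gm.phased and gm.haplotypes is not None else "/"
        for i in range(gm.n_sites):
            cells = []
            for j in range(gm.n_samples):
                if gm.phased and gm.haplotypes is not None:
                    a, b = gm.haplotypes[i, 2 * j], gm.haplotypes[i, 2 * j + 1]
                    gt = "./." if a == MISSING or b == MISSING else f"{a}{sep}{b}"
                else:
                    d = gm.dosages[i, j]
                    gt = "./." if d == MISSING else {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
                if gm.depth is not None:
                    dp = gm.depth[i, j]
                    gt += ":." if dp == MISSING else f":{int(dp)}"
                cells.append(gt)
            s = gm.sites.iloc[i]
            qual = "." if pd.isna(s["qual"]) else f"{s['qual']:g}"
            fh.write(
                f"{s['chrom']}\t{s['pos']}\t{s['site_id']}\t{s['ref']}\t{s['alt']}"
                f"\t{qual}\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )
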