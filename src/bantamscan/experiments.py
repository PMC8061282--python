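"""Replicate-level evaluation of the full inference chain on simulated data.

One replicate = one bantamization simulation at the default study conditions,
followed by the per-group mixed-model scans, the fixed-effects meta-analysis,
and the group-1 introgression statistics (windowed F_ST and rIBD). The
summary captures how well each stage recovers the planted truth: lead-variant
distance to the causal locus, meta-analysis power at the shared locus,
heterogeneity at the group-private locus, and the regional F_ST/rIBD
contrasts.

Simulation-scale analysis constants: the IBD detection threshold is 0.3 cM —
the swept-haplotype scale (2 x 50 kb x 3 cM/Mb) and ~2.5x the background
match-run length at the simulated marker density (the 0.03 cM criterion used
on multi-million-variant panels saturates at this density). The rIBD causal
region is the 100-kb window centered on the locus; the regional F_ST
contrast is measured over +-100 kb, just beyond the swept core, where both
cohort comparisons stay polymorphic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gwas, introgression, meta
from .simdata import SimConfig, simulate

__all__ = ["replicate_summary", "SIM_MIN_CM", "RIBD_REGION_BP", "FST_REGION_BP"]

SIM_MIN_CM = 0.3
RIBD_REGION_BP = 50_000
FST_REGION_BP = 100_000


def _p_at(df: pd.DataFrame, chrom: str, pos: int) -> float:
    row = df[(df["chrom"] == chrom) & (df["pos"] == pos)]
    return float(row["p"].iloc[0]) if len(row) else float("nan")


def replicate_summary(seed: int, config: SimConfig | None = None) -> dict:
    """Simulate one replicate and evaluate every stage against the truth."""
    cfg = config if config is not None else SimConfig(seed=seed)
    pop = simulate(cfg)
    gm = pop.to_genotype_matrix()
    samples = pop.samples
    lengths = cfg.chrom_lengths()

    out: dict = {"seed": seed, "groups": {}}
    scans = []
    for g in sorted(pop.causal_loci):
        scan, summ = gwas.run_group_scan(gm, samples, g)
        scans.append(scan)
        chrom, pos = pop.causal_loci[g]
        scored = scan[scan["stat"].notna()]
        lead = scored.loc[scored["stat"].idxmax()]
        dist = abs(int(lead["pos"]) - pos) if lead["chrom"] == chrom else np.inf
        out["groups"][g] = {
            "lambda_gc": summ.lambda_gc,
            "n_significant": summ.n_significant,
            "lead_dist_bp": float(dist),
            "p_at_causal": _p_at(scan, chrom, pos),
        }

    table, msum = meta.run_meta(scans)
    out["meta"] = {
        "n_significant": msum["n_significant"],
        "het_fraction_significant": msum["het_fraction_significant"],
        "lambdas": msum["lambdas"],
    }

    # shared locus: carried by >1 group; private locus: carried by exactly one
    by_locus: dict[tuple, list[int]] = {}
    for g, locus in pop.causal_loci.items():
        by_locus.setdefault(locus, []).append(g)
    shared = [(loc, gs) for loc, gs in by_locus.items() if len(gs) > 1]
    private = [(loc, gs[0]) for loc, gs in by_locus.items() if len(gs) == 1]
    if shared:
        (chrom, pos), gs = shared[0]
        group_ps = [_p_at(scans[g - 1], chrom, pos) for g in gs]
        out["shared_locus"] = {
            "meta_p": _p_at(table, chrom, pos),
            "min_group_p": float(np.nanmin(group_ps)),
        }
    if private:
        (chrom, pos), g = private[0]
        row = table[(table["chrom"] == chrom) & (table["pos"] == pos)]
        out["private_locus"] = {
            "group": g,
            "p_het": float(row["p_het"].iloc[0]) if len(row) else float("nan"),
            "meta_p": _p_at(table, chrom, pos),
        }

    # group-1 introgression scan (the shared-locus group)
    grp = samples[samples["group"] == 1]
    ids = {
        r: list(grp.loc[grp["role"] == r, "sample_id"])
        for r in ("source", "neo_bantam", "counterpart")
    }
    segments = pd.concat(
        [
            introgression.detect_ibd(gm, ids["source"], ids["neo_bantam"], pop.gmap, SIM_MIN_CM),
            introgression.detect_ibd(gm, ids["counterpart"], ids["neo_bantam"], pop.gmap, SIM_MIN_CM),
        ],
        ignore_index=True,
    )
    track = introgression.ribd_scan(segments, samples, 1, chrom_lengths=lengths)
    chrom, pos = pop.causal_loci[1]
    in_region = (
        (track["chrom"] == chrom)
        & (track["start"] >= pos - RIBD_REGION_BP)
        & (track["end"] <= pos + RIBD_REGION_BP)
    )
    out["ribd"] = {
        "region_mean": float(track.loc[in_region, "ribd"].mean()),
        "genome_mean": float(track["ribd"].mean()),
        "q99": float(np.percentile(track["ribd"], 99)),
    }

    region = [(chrom, pos - FST_REGION_BP, pos + FST_REGION_BP)]
    fst = {}
    for other in ("source", "counterpart"):
        t = introgression.fst_scan(gm, ids["neo_bantam"], ids[other], chrom_lengths=lengths)
        s = introgression.mean_fst_summary(t, regions=region)
        fst[f"genome_mean_neo_{other}"] = s["mean"]
        fst[f"region_mean_neo_{other}"] = s[f"{chrom}:{pos - FST_REGION_BP}-{pos + FST_REGION_BP}"]
    out["fst"] = fst
    return out
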