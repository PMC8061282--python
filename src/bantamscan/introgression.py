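"""Windowed Weir-Cockerham F_ST and relative IBD (rIBD) introgression mapping.

F_ST uses the Weir & Cockerham (1984) variance components a (among
populations), b (among individuals within populations) and c (within
individuals) for two populations of diploids, including the unequal-sample-
size corrections, and the windowed ratio-of-sums estimator
sum(a) / sum(a + b + c) over 10-kb tiles — the weighted window estimator.

IBD segments between phased haplotypes are found with a deterministic
identity-run detector: maximal runs of allele identity allowing a bounded
number of mismatches, reported when their genetic length reaches the
detection threshold (default 0.03 cM, deliberately permissive so that
population-level sharing, not single-coancestor segments, is captured).
Externally detected segments (Refined-IBD-style tab files) are accepted
interchangeably.

The introgression statistic compares, per 10-kb window, the normalized count
of IBD-sharing haplotype pairs between the true-bantam source and the
neo-bantams (nIBD = cIBD / tIBD) against the same quantity between the
normal-sized counterpart and the neo-bantams: rIBD = nIBD_source_neo -
nIBD_counterpart_neo. Positive rIBD marks regions where neo-bantam
haplotypes resemble the bantam source — introgression candidates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .genmap import GeneticMap

__all__ = [
    "wc_fst_site",
    "wc_fst_components",
    "fst_windows",
    "fst_scan",
    "detect_ibd",
    "read_ibd_file",
    "write_ibd_file",
    "ribd_scan",
    "mean_fst_summary",
    "WINDOW_BP",
]

WINDOW_BP = 10_000
IBD_COLUMNS = ["sample1", "hap1", "sample2", "hap2", "chrom", "start", "end", "score"]


# ------------------------------------------------------------------- W&C F_ST


def wc_fst_components(
    g1: np.ndarray, g2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site variance components for two populations.

    ``g1``/``g2`` are (m_sites, n_ind) dosage matrices (0/1/2, MISSING).
    Returns (a, b, c, informative). Sites monomorphic across both
    populations, or with fewer than two genotyped individuals in either,
    are flagged uninformative with zero components.
    """
    comps = []
    ok = []
    r = 2.0
    for g in (g1, g2):
        g = np.asarray(g)
        m = g != MISSING
        n = m.sum(axis=1).astype(float)  # diploid individuals genotyped
        alt = np.where(m, g, 0).astype(float).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = np.where(m, g == 1, False).sum(axis=1) / n  # obs het proportion
        comps.append((n, p, h))
        ok.append(n >= 2)
    (n1, p1, h1), (n2, p2, h2) = comps
    informative = ok[0] & ok[1]

    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    poly = informative & (pbar > 0) & (pbar < 1)
    a = np.where(poly, a, 0.0)
    b = np.where(poly, b, 0.0)
    c = np.where(poly, c, 0.0)
    return a, b, c, poly


def wc_fst_site(geno_pop1: np.ndarray, geno_pop2: np.ndarray) -> tuple[float, float, float, bool]:
    """Single-site convenience wrapper around :func:`wc_fst_components`."""
    a, b, c, ok = wc_fst_components(
        np.atleast_2d(np.asarray(geno_pop1)), np.atleast_2d(np.asarray(geno_pop2))
    )
    return float(a[0]), float(b[0]), float(c[0]), bool(ok[0])


def fst_windows(
    sites: pd.DataFrame,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    informative: np.ndarray,
    window_bp: int = WINDOW_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Ratio-of-sums window track: F_ST = sum(a) / sum(a+b+c) per tile.

    Windows tile each chromosome as [k*w, (k+1)*w) in 0-based bp; windows
    without informative sites carry NaN.
    """
    chrom_arr = sites["chrom"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1  # 0-based
    rows = []
    lengths = chrom_lengths or {
        ch: int(sites.loc[sites["chrom"] == ch, "pos"].max())
        for ch in dict.fromkeys(chrom_arr)
    }
    for chrom, length in lengths.items():
        in_chrom = chrom_arr == chrom
        widx = pos0[in_chrom] // window_bp
        num = a[in_chrom] * informative[in_chrom]
        den = (a[in_chrom] + b[in_chrom] + c[in_chrom]) * informative[in_chrom]
        n_windows = int(np.ceil(length / window_bp))
        sum_a = np.bincount(widx, weights=num, minlength=n_windows)
        sum_abc = np.bincount(widx, weights=den, minlength=n_windows)
        n_inf = np.bincount(widx, weights=informative[in_chrom].astype(float), minlength=n_windows)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where((n_inf > 0) & (sum_abc != 0), sum_a / sum_abc, np.nan)
        for k in range(n_windows):
            rows.append(
                (chrom, k * window_bp, (k + 1) * window_bp, int(n_inf[k]), fst[k])
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "fst"])


def fst_scan(
    gm: GenotypeMatrix,
    ids_pop1: list[str],
    ids_pop2: list[str],
    window_bp: int = WINDOW_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST between two sample cohorts."""
    g1 = gm.take_samples(ids_pop1).dosages
    g2 = gm.take_samples(ids_pop2).dosages
    a, b, c, ok = wc_fst_components(g1, g2)
    return fst_windows(gm.sites, a, b, c, ok, window_bp, chrom_lengths)


def mean_fst_summary(track: pd.DataFrame, regions: list[tuple[str, int, int]] | None = None) -> dict:
    """Genome-wide mean/median window F_ST, plus per-region means.

    NaN windows (no informative sites) are excluded. Regions are
    (chrom, start_bp, end_bp), 0-based half-open against window starts.
    """
    vals = track["fst"].dropna()
    if vals.empty:
        raise ValueError("empty F_ST track")
    out = {"mean": float(vals.mean()), "median": float(vals.median())}
    for chrom, start, end in regions or ():
        sel = track[
            (track["chrom"] == chrom) & (track["end"] > start) & (track["start"] < end)
        ]["fst"].dropna()
        out[f"{chrom}:{start}-{end}"] = float(sel.mean()) if len(sel) else float("nan")
    return out


# ------------------------------------------------------------------ IBD detect


def _pair_segments(
    h1: np.ndarray,
    h2: np.ndarray,
    pos: np.ndarray,
    cm: np.ndarray,
    min_cm: float,
    max_mismatches: int,
) -> list[tuple[int, int, float, int]]:
    """Maximal identity runs with <= max_mismatches internal mismatches.

    Runs are delimited by mismatch sentinels: the run between mismatch i and
    mismatch i + max_mismatches + 1 (exclusive) is maximal, never starts or
    ends on a mismatch, and contains at most max_mismatches of them.
    Returns (start_bp, end_bp, length_cm, n_sites) tuples.
    """
    diff = np.flatnonzero((h1 != h2) | (h1 == MISSING) | (h2 == MISSING))
    bounds = np.concatenate([[-1], diff, [len(h1)]])
    step = max_mismatches + 1
    if len(bounds) <= step:
        s_idx = np.array([0]) if len(h1) else np.empty(0, dtype=int)
        e_idx = np.array([len(h1) - 1]) if len(h1) else np.empty(0, dtype=int)
    else:
        s_idx = bounds[: len(bounds) - step] + 1
        e_idx = bounds[step:] - 1
    good = e_idx > s_idx
    s_idx, e_idx = s_idx[good], e_idx[good]
    lengths = cm[e_idx] - cm[s_idx]
    keep = lengths >= min_cm
    return [
        (int(pos[s]), int(pos[e]), float(L), int(e - s + 1))
        for s, e, L in zip(s_idx[keep], e_idx[keep], lengths[keep])
    ]


def detect_ibd(
    gm: GenotypeMatrix,
    ids_a: list[str],
    ids_b: list[str],
    gmap: GeneticMap,
    min_length_cm: float = 0.03,
    max_mismatches: int = 1,
) -> pd.DataFrame:
    """IBD segments between every haplotype of cohort A and cohort B.

    Requires phased input. The score column is the number of matching sites
    in the run. Segment coordinates are the 1-based positions of the first
    and last site of the run (inclusive).
    """
    if not gm.phased or gm.haplotypes is None:
        raise ValueError("IBD detection requires phased haplotypes")
    sample_pos = {s: i for i, s in enumerate(gm.samples)}
    chrom_arr = gm.sites["chrom"].to_numpy()
    pos_arr = gm.sites["pos"].to_numpy()
    rows = []
    for chrom in dict.fromkeys(chrom_arr):
        sel = chrom_arr == chrom
        pos = pos_arr[sel]
        cm = np.asarray(gmap.bp_to_cm(chrom, pos), dtype=float)
        H = gm.haplotypes[sel]
        for sa in ids_a:
            for ha in (1, 2):
                va = H[:, 2 * sample_pos[sa] + ha - 1]
                for sb in ids_b:
                    if sb == sa:
                        continue
                    for hb in (1, 2):
                        vb = H[:, 2 * sample_pos[sb] + hb - 1]
                        for s, e, L, nsites in _pair_segments(
                            va, vb, pos, cm, min_length_cm, max_mismatches
                        ):
                            rows.append((sa, ha, sb, hb, chrom, s, e, L, nsites))
    return pd.DataFrame(
        rows, columns=IBD_COLUMNS[:7] + ["length_cm", "score"]
    ).astype({"start": int, "end": int})


def write_ibd_file(segments: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited Refined-IBD-style output (no header)."""
    segments[IBD_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_ibd_file(path: str | Path, gmap: GeneticMap | None = None) -> pd.DataFrame:
    """Parse a Refined-IBD-style tab file into the internal segment table.

    Columns: sample1, hap1, sample2, hap2, chrom, start, end, LOD. Start/end
    are 1-based inclusive, as emitted by Refined-IBD and by
    :func:`write_ibd_file`. Genetic lengths are recomputed when a map is
    given. Malformed lines raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 columns, got {len(parts)}")
            try:
                rows.append(
                    (
                        parts[0],
                        int(parts[1]),
                        parts[2],
                        int(parts[3]),
                        parts[4],
                        int(parts[5]),
                        int(parts[6]),
                        float(parts[7]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=IBD_COLUMNS)
    if (df["start"] >= df["end"]).any():
        bad = int((df["start"] >= df["end"]).sum())
        raise ValueError(f"{path}: {bad} segments with start >= end")
    if gmap is not None:
        df["length_cm"] = [
            float(gmap.bp_to_cm(c, e) - gmap.bp_to_cm(c, s))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
    return df


# ------------------------------------------------------------------ rIBD scan


def _window_pair_sharing(
    segments: pd.DataFrame,
    haps_x: list[tuple[str, int]],
    haps_n: list[tuple[str, int]],
    window_bp: int,
    window_offsets: dict[str, tuple[int, int]],
    n_windows_total: int,
) -> np.ndarray:
    """cIBD per window: number of (X, N) haplotype pairs with >=1 overlapping
    segment. Any overlap with the window counts."""
    pair_idx = {
        (a, b): i * len(haps_n) + j
        for i, a in enumerate(haps_x)
        for j, b in enumerate(haps_n)
    }
    seen = np.zeros((n_windows_total, len(pair_idx)), dtype=bool)
    for row in segments.itertuples(index=False):
        key = ((row.sample1, row.hap1), (row.sample2, row.hap2))
        if key not in pair_idx:
            key = ((row.sample2, row.hap2), (row.sample1, row.hap1))
            if key not in pair_idx:
                continue
        col = pair_idx[key]
        off, nw = window_offsets[row.chrom]
        w0 = max((row.start - 1) // window_bp, 0)
        w1 = min((row.end - 1) // window_bp, nw - 1)
        seen[off + w0 : off + w1 + 1, col] = True
    return seen.sum(axis=1)


def ribd_scan(
    segments: pd.DataFrame,
    samples: pd.DataFrame,
    group_id: int,
    window_bp: int = WINDOW_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Window track of cIBD/tIBD/nIBD for source<->neo and counterpart<->neo,
    and their difference rIBD.

    Cohorts come from the sample table roles within the group: true-bantam
    sources (A), neo-bantams (N) and normal-sized counterparts (C); tIBD is
    the number of haplotype pairs, 2|X| * 2|N|.
    """
    grp = samples[samples["group"] == group_id]
    ids_a = list(grp.loc[grp["role"] == "source", "sample_id"])
    ids_n = list(grp.loc[grp["role"] == "neo_bantam", "sample_id"])
    ids_c = list(grp.loc[grp["role"] == "counterpart", "sample_id"])
    if not (ids_a and ids_n and ids_c):
        raise ValueError(f"group {group_id}: missing one of the three cohorts")

    if chrom_lengths is None:
        chrom_lengths = {
            ch: int(segments.loc[segments["chrom"] == ch, "end"].max())
            for ch in dict.fromkeys(segments["chrom"])
        }
    window_offsets: dict[str, tuple[int, int]] = {}
    off = 0
    rows = []
    for chrom, length in chrom_lengths.items():
        nw = int(np.ceil(length / window_bp))
        window_offsets[chrom] = (off, nw)
        for k in range(nw):
            rows.append((chrom, k * window_bp, (k + 1) * window_bp))
        off += nw
    track = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    haps = lambda ids: [(s, h) for s in ids for h in (1, 2)]  # noqa: E731
    out = {}
    for name, ids_x in (("source", ids_a), ("counterpart", ids_c)):
        hx, hn = haps(ids_x), haps(ids_n)
        cibd = _window_pair_sharing(
            segments, hx, hn, window_bp, window_offsets, len(track)
        )
        tibd = len(hx) * len(hn)
        out[f"cibd_{name}_neo"] = cibd
        out[f"tibd_{name}_neo"] = tibd
        out[f"nibd_{name}_neo"] = cibd / tibd
    for k, v in out.items():
        track[k] = v
    track["ribd"] = track["nibd_source_neo"] - track["nibd_counterpart_neo"]
    return track
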