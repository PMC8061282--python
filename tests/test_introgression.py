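"""Weir-Cockerham F_ST (sites and windows), IBD detection, rIBD scan."""

import numpy as np
import pandas as pd
import pytest

from bantamscan import introgression as intro
from bantamscan.containers import MISSING, GenotypeMatrix
from bantamscan.genmap import GeneticMap
from bantamscan.simdata import SimConfig, simulate

from oracles import wc_abc_scalar, wc_fst_window_scalar


def make_phased_gm(haps, positions=None, chrom="chr1"):
    haps = np.asarray(haps, dtype=np.int8)
    m, two_n = haps.shape
    n = two_n // 2
    pos = np.asarray(positions) if positions is not None else np.arange(1, m + 1) * 1000
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "qual": 50.0,
            "site_id": [f"v{i}" for i in range(m)],
        }
    )
    return GenotypeMatrix(
        sites=sites,
        samples=[f"s{i}" for i in range(n)],
        dosages=haps[:, 0::2] + haps[:, 1::2],
        phased=True,
        haplotypes=haps,
    )


# --------------------------------------------------------------------- F_ST


def test_fixed_difference_site_gives_fst_one():
    g1 = np.full((1, 40), 2, dtype=np.int8)
    g2 = np.zeros((1, 40), dtype=np.int8)
    a, b, c, ok = intro.wc_fst_components(g1, g2)
    assert ok[0]
    assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0)


def test_null_site_fst_near_zero(rng):
    g1 = rng.binomial(2, 0.4, size=(2000, 25)).astype(np.int8)
    g2 = rng.binomial(2, 0.4, size=(2000, 25)).astype(np.int8)
    a, b, c, ok = intro.wc_fst_components(g1, g2)
    fst = a[ok].sum() / (a + b + c)[ok].sum()
    assert abs(fst) < 0.01


def test_monomorphic_site_flagged_uninformative():
    g1 = np.zeros((1, 10), dtype=np.int8)
    g2 = np.zeros((1, 10), dtype=np.int8)
    a, b, c, ok = intro.wc_fst_components(g1, g2)
    assert not ok[0] and a[0] == b[0] == c[0] == 0.0


def test_components_match_scalar_oracle(rng):
    for _ in range(100):
        n1, n2 = rng.integers(5, 51, size=2)
        g1 = rng.integers(0, 3, size=(1, n1)).astype(np.int8)
        g2 = rng.integers(0, 3, size=(1, n2)).astype(np.int8)
        g1[0, rng.random(n1) < 0.1] = MISSING
        g2[0, rng.random(n2) < 0.1] = MISSING
        a, b, c, ok = intro.wc_fst_components(g1, g2)
        oracle = wc_abc_scalar(list(g1[0]), list(g2[0]))
        if oracle is None:
            assert not ok[0]
        else:
            assert ok[0]
            assert abs(a[0] - oracle[0]) < 1e-12
            assert abs(b[0] - oracle[1]) < 1e-12
            assert abs(c[0] - oracle[2]) < 1e-12


def test_window_ratio_of_sums_differs_from_mean_of_ratios():
    # two sites in one window with very different magnitudes
    g1 = np.array([[2] * 20 + [1] * 0, [1] * 4 + [0] * 16], dtype=np.int8)
    g2 = np.array([[0] * 20, [0] * 4 + [1] * 16], dtype=np.int8)
    sites = pd.DataFrame({"chrom": "chr1", "pos": [100, 200]})
    a, b, c, ok = intro.wc_fst_components(g1, g2)
    track = intro.fst_windows(sites, a, b, c, ok, window_bp=10_000, chrom_lengths={"chr1": 10_000})
    ratio_of_sums = track["fst"].iloc[0]
    per_site = a / (a + b + c)
    assert ratio_of_sums == pytest.approx(
        wc_fst_window_scalar([list(g1[0]), list(g1[1])], [list(g2[0]), list(g2[1])])
    )
    assert abs(ratio_of_sums - per_site.mean()) > 1e-3


def test_single_site_window_equals_site_value():
    g1 = np.array([[2] * 10 + [1] * 10], dtype=np.int8)
    g2 = np.array([[0] * 15 + [1] * 5], dtype=np.int8)
    a, b, c, ok = intro.wc_fst_components(g1, g2)
    sites = pd.DataFrame({"chrom": "chr1", "pos": [5000]})
    track = intro.fst_windows(sites, a, b, c, ok, chrom_lengths={"chr1": 20_000})
    assert track["fst"].iloc[0] == pytest.approx(a[0] / (a[0] + b[0] + c[0]))
    assert np.isnan(track["fst"].iloc[1])  # empty window


def test_mean_fst_summary_excludes_na_windows():
    track = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [0, 10_000, 20_000],
            "end": [10_000, 20_000, 30_000],
            "n_sites": [1, 0, 1],
            "fst": [0.2, np.nan, 0.4],
        }
    )
    out = intro.mean_fst_summary(track, regions=[("chr1", 0, 10_000)])
    assert out["mean"] == pytest.approx(0.3)
    assert out["chr1:0-10000"] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        intro.mean_fst_summary(track.assign(fst=np.nan))


# ---------------------------------------------------------------------- IBD


def test_identical_haplotypes_give_one_spanning_segment():
    m = 50
    hapA = np.tile(np.array([0, 1], dtype=np.int8), m // 2)
    haps = np.column_stack([hapA, 1 - hapA, hapA, np.zeros(m, dtype=np.int8)])
    pos = np.linspace(1, 5_000_000, m).astype(int)
    gm = make_phased_gm(haps, positions=pos)
    gmap = GeneticMap.constant_rate({"chr1": 5_000_000}, 1.0)  # 5 cM
    segs = intro.detect_ibd(gm, ["s0"], ["s1"], gmap, min_length_cm=0.03)
    spanning = segs[(segs["hap1"] == 1) & (segs["hap2"] == 1)]
    assert len(spanning) == 1
    assert spanning.iloc[0]["start"] == pos[0] and spanning.iloc[0]["end"] == pos[-1]


def test_run_below_length_threshold_not_reported():
    m = 10
    hapA = np.zeros(m, dtype=np.int8)
    haps = np.column_stack([hapA, hapA, hapA, hapA])
    pos = np.linspace(1, 20_000, m).astype(int)  # 0.02 cM at 1 cM/Mb
    gm = make_phased_gm(haps, positions=pos)
    gmap = GeneticMap.constant_rate({"chr1": 20_000}, 1.0)
    segs = intro.detect_ibd(gm, ["s0"], ["s1"], gmap, min_length_cm=0.03)
    assert segs.empty


def test_detector_is_symmetric(demo_gm, demo_pop):
    gmap = demo_pop.gmap
    a = intro.detect_ibd(demo_gm, ["g1_src1"], ["g1_neo1"], gmap, 0.3)
    b = intro.detect_ibd(demo_gm, ["g1_neo1"], ["g1_src1"], gmap, 0.3)
    key_a = {(r.hap1, r.hap2, r.chrom, r.start, r.end) for r in a.itertuples()}
    key_b = {(r.hap2, r.hap1, r.chrom, r.start, r.end) for r in b.itertuples()}
    assert key_a == key_b


def test_f1_shares_half_its_genome_with_source_cohort():
    """F1 hybrids carry one source-derived genome copy, so the union of their
    IBD segments with the source cohort covers about half the genome."""
    cfg = SimConfig(seed=31, n_groups=1, n_backcross_generations=0,
                    n_maintenance_generations=0, n_chromosomes=2,
                    n_sites_per_chromosome=800, n_source=4, n_counterpart=8,
                    n_neo=8, breeding_pool_size=12)
    pop = simulate(cfg)
    gm = pop.to_genotype_matrix()
    src = [s for s in gm.samples if "src" in s]
    neo = [s for s in gm.samples if "neo" in s]
    segs = intro.detect_ibd(gm, src, neo, pop.gmap, min_length_cm=1.0)
    L = cfg.chromosome_length_bp * cfg.n_chromosomes
    covs = []
    for s in neo:
        sub = segs[segs["sample2"] == s]
        covered = 0
        for (chrom, hap), grp in sub.groupby(["chrom", "hap2"]):
            iv = sorted(zip(grp["start"], grp["end"]))
            last = -1
            for st, en in iv:
                covered += max(0, en - max(st, last))
                last = max(last, en)
        covs.append(covered / (2 * L))
    assert abs(np.mean(covs) - 0.5) < 0.12


def test_ibd_file_round_trip(tmp_path, demo_gm, demo_pop):
    segs = intro.detect_ibd(demo_gm, ["g1_src1"], ["g1_neo1"], demo_pop.gmap, 0.3)
    path = tmp_path / "segs.ibd"
    intro.write_ibd_file(segs, path)
    back = intro.read_ibd_file(path, demo_pop.gmap)
    assert len(back) == len(segs)
    assert np.array_equal(back["start"].to_numpy(), segs["start"].to_numpy())
    assert np.allclose(back["score"].to_numpy(), segs["score"].to_numpy())
    assert "length_cm" in back


def test_ibd_reader_rejects_malformed_lines(tmp_path):
    p = tmp_path / "bad.ibd"
    p.write_text("s1\t1\ts2\t1\tchr1\t100\n")
    with pytest.raises(ValueError, match="bad.ibd:1"):
        intro.read_ibd_file(p)
    p.write_text("")
    assert intro.read_ibd_file(p).empty


# ---------------------------------------------------------------------- rIBD


def toy_samples():
    return pd.DataFrame(
        {
            "sample_id": ["a1", "n1", "c1"],
            "breed": ["x", "y", "z"],
            "size_class": ["bantam", "bantam", "normal"],
            "role": ["source", "neo_bantam", "counterpart"],
            "group": [1, 1, 1],
        }
    )


def test_ribd_bounds_with_complete_sharing():
    segs = pd.DataFrame(
        [
            ("a1", h1, "n1", h2, "chr1", 1, 10_000, 5.0)
            for h1 in (1, 2)
            for h2 in (1, 2)
        ],
        columns=intro.IBD_COLUMNS,
    )
    track = intro.ribd_scan(segs, toy_samples(), 1, chrom_lengths={"chr1": 20_000})
    w0 = track.iloc[0]
    assert w0["nibd_source_neo"] == 1.0 and w0["ribd"] == 1.0
    assert track["cibd_source_neo"].le(track["tibd_source_neo"]).all()
    assert track["ribd"].between(-1, 1).all()


def test_ribd_zero_without_segments():
    segs = pd.DataFrame(columns=intro.IBD_COLUMNS)
    track = intro.ribd_scan(segs, toy_samples(), 1, chrom_lengths={"chr1": 30_000})
    assert (track["ribd"] == 0).all()
    assert len(track) == 3


def test_ribd_requires_all_cohorts():
    segs = pd.DataFrame(columns=intro.IBD_COLUMNS)
    samples = toy_samples()[lambda d: d["role"] != "source"]
    with pytest.raises(ValueError):
        intro.ribd_scan(segs, samples, 1, chrom_lengths={"chr1": 10_000})


def test_ribd_track_invariants_on_simulation(demo_gm, demo_pop):
    samples = demo_pop.samples
    grp = samples[samples["group"] == 1]
    ids = {
        r: list(grp.loc[grp["role"] == r, "sample_id"])
        for r in ("source", "neo_bantam", "counterpart")
    }
    lengths = {c: demo_pop.config.chromosome_length_bp for c in demo_pop.gmap.chromosomes}
    segs = pd.concat(
        [
            intro.detect_ibd(demo_gm, ids["source"], ids["neo_bantam"], demo_pop.gmap, 0.3),
            intro.detect_ibd(demo_gm, ids["counterpart"], ids["neo_bantam"], demo_pop.gmap, 0.3),
        ],
        ignore_index=True,
    )
    track = intro.ribd_scan(segs, samples, 1, chrom_lengths=lengths)
    assert track["ribd"].between(-1, 1).all()
    assert (track["cibd_source_neo"] <= track["tibd_source_neo"]).all()
    assert (track["nibd_source_neo"].between(0, 1)).all()
    chrom, pos = demo_pop.causal_loci[1]
    reg = track[
        (track["chrom"] == chrom)
        & (track["start"] >= pos - 50_000)
        & (track["end"] <= pos + 50_000)
    ]
    assert reg["ribd"].mean() > 0
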