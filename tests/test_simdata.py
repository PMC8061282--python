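"""Simulator: founder model, meiosis, crossbreeding design, truth tracks, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bantamscan.genmap import GeneticMap
from bantamscan.introgression import wc_fst_components
from bantamscan.simdata import (
    CausalLocus,
    SimConfig,
    _SiteLayout,
    generate_founders,
    plant_causal_locus,
    recombine,
    simulate,
    simulate_cross,
    write_outputs,
)
from bantamscan.variant_qc import read_vcf

TINY = dict(
    n_chromosomes=2,
    n_sites_per_chromosome=300,
    n_source=4,
    n_counterpart=8,
    n_neo=6,
    breeding_pool_size=12,
    n_maintenance_generations=2,
)


# ------------------------------------------------------------------ founders


def test_seeded_founders_are_bit_reproducible():
    a = generate_founders(SimConfig(seed=5, **TINY))
    b = generate_founders(SimConfig(seed=5, **TINY))
    for breed in a.cohorts:
        assert np.array_equal(a.cohorts[breed], b.cohorts[breed])
        assert np.array_equal(a.breed_freqs[breed], b.breed_freqs[breed])
    c = generate_founders(SimConfig(seed=6, **TINY))
    assert not np.array_equal(a.cohorts["group1_source"], c.cohorts["group1_source"])


def test_no_drift_limit_gives_zero_fst():
    cfg = SimConfig(seed=2, n_groups=1, breed_divergence_F=0.0,
                    n_chromosomes=1, n_sites_per_chromosome=2000,
                    n_source=30, n_counterpart=30)
    panel = generate_founders(cfg)
    assert np.array_equal(
        panel.breed_freqs["group1_source"], panel.breed_freqs["group1_counterpart"]
    )
    g1 = panel.cohorts["group1_source"][:, 0::2] + panel.cohorts["group1_source"][:, 1::2]
    g2 = panel.cohorts["group1_counterpart"][:, 0::2] + panel.cohorts["group1_counterpart"][:, 1::2]
    a, b, c, ok = wc_fst_components(g1, g2)
    fst = a[ok].sum() / (a + b + c)[ok].sum()
    assert abs(fst) < 0.01


def test_balding_nichols_drift_recovered_as_fst():
    """Two breeds drifted with F=0.2 show Weir-Cockerham F_ST ~ 0.2."""
    cfg = SimConfig(seed=3, n_groups=1, breed_divergence_F=0.2,
                    n_chromosomes=1, n_sites_per_chromosome=5000,
                    n_source=40, n_counterpart=40)
    panel = generate_founders(cfg)
    g1 = panel.cohorts["group1_source"][:, 0::2] + panel.cohorts["group1_source"][:, 1::2]
    g2 = panel.cohorts["group1_counterpart"][:, 0::2] + panel.cohorts["group1_counterpart"][:, 1::2]
    a, b, c, ok = wc_fst_components(g1, g2)
    fst = a[ok].sum() / (a + b + c)[ok].sum()
    assert abs(fst - 0.2) < 0.02


def test_breed_frequency_distribution_matches_balding_nichols():
    """With a (nearly) fixed ancestral frequency 0.5 and F=0.2 the breed
    frequencies follow Beta(2, 2)."""
    cfg = SimConfig(seed=9, n_groups=1, breed_divergence_F=0.2,
                    ancestral_freq_distribution=(5000.0, 5000.0),
                    n_chromosomes=1, n_sites_per_chromosome=2000)
    panel = generate_founders(cfg)
    q = panel.breed_freqs["group1_source"]
    assert stats.kstest(q, "beta", args=(2, 2)).pvalue > 1e-3


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(seed=1, breed_divergence_F=1.0)
    with pytest.raises(ValueError):
        SimConfig(seed=1, n_source=0)
    with pytest.raises(ValueError):
        SimConfig(seed=1, causal_loci=[CausalLocus("chr1", 10**9, (1,))])
    with pytest.raises(ValueError):
        SimConfig(seed=1, selection_mode="strongest")


# --------------------------------------------------------------- plant locus


def test_planted_locus_fixed_difference():
    cfg = SimConfig(seed=4, **TINY)
    panel = generate_founders(cfg)
    locus = CausalLocus("chr1", 4_000_000, (1,))
    plant_causal_locus(panel, locus, source_freq=1.0, counterpart_freq=0.0)
    i = panel.causal_sites[1]
    assert panel.cohorts["group1_source"][i].all()
    assert not panel.cohorts["group1_counterpart"][i].any()


def test_planted_frequency_is_binomial():
    cfg = SimConfig(seed=4, n_groups=1, n_source=60, n_counterpart=5,
                    n_chromosomes=1, n_sites_per_chromosome=200)
    panel = generate_founders(cfg)
    plant_causal_locus(panel, CausalLocus("chr1", 4_000_000, (1,)), source_freq=0.9)
    i = panel.causal_sites[1]
    freq = panel.cohorts["group1_source"][i].mean()
    # 120 haplotypes at 0.9: allow 3 binomial sigmas
    assert abs(freq - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 120)


def test_plant_rejects_bad_frequency():
    panel = generate_founders(SimConfig(seed=4, **TINY))
    with pytest.raises(ValueError):
        plant_causal_locus(panel, CausalLocus("chr1", 1000, (1,)), source_freq=1.5)


def test_inserted_site_keeps_positions_sorted():
    panel = generate_founders(SimConfig(seed=4, **TINY))
    plant_causal_locus(panel, CausalLocus("chr2", 1_234_567, (1,)))
    sub = panel.sites[panel.sites["chrom"] == "chr2"]["pos"].to_numpy()
    assert (np.diff(sub) > 0).all()
    assert (panel.sites["pos"] == 1_234_567).any()


# ------------------------------------------------------------------- meiosis


def _two_founder_parents(cfg, panel):
    from bantamscan.simdata import _founder_haplotype

    return (
        _founder_haplotype(panel, "group1_source", 0, "source"),
        _founder_haplotype(panel, "group1_counterpart", 0, "counterpart"),
    )


def test_zero_length_map_returns_intact_parent():
    cfg = SimConfig(seed=8, **TINY)
    panel = generate_founders(cfg)
    flat = GeneticMap(
        {c: np.array([[0.0, 0.0], [cfg.chromosome_length_bp, 0.0]])
         for c in cfg.chrom_names()}
    )
    layout = _SiteLayout(panel.sites, flat)
    pa, pb = _two_founder_parents(cfg, panel)
    rng = np.random.default_rng(0)
    for _ in range(5):
        g = recombine((pa, pb), layout, rng)
        for chrom in cfg.chrom_names():
            sl = layout.slices[chrom]
            assert np.array_equal(g.alleles[sl], pa.alleles[sl]) or np.array_equal(
                g.alleles[sl], pb.alleles[sl]
            )


def test_crossover_count_is_poisson_in_map_length():
    """A 1-Morgan chromosome yields ~Poisson(1) crossovers per meiosis."""
    cfg = SimConfig(seed=8, n_groups=1, n_chromosomes=1,
                    chromosome_length_bp=1_000_000, n_sites_per_chromosome=50,
                    recombination_rate=100.0)  # 100 cM over 1 Mb
    panel = generate_founders(cfg)
    layout = _SiteLayout(panel.sites, cfg.genetic_map())
    pa, pb = _two_founder_parents(cfg, panel)
    rng = np.random.default_rng(1)
    n_gametes = 10_000
    counts = np.empty(n_gametes)
    for i in range(n_gametes):
        g = recombine((pa, pb), layout, rng)
        counts[i] = len(g.segments["chr1"]) - 1
    se = counts.std(ddof=1) / np.sqrt(n_gametes)
    assert abs(counts.mean() - 1.0) <= 3 * se


def test_map_interpolation_round_trip():
    gmap = GeneticMap.constant_rate({"chr1": 8_000_000}, 3.0)
    pos = np.array([1, 17, 123_456, 7_999_999])
    back = gmap.cm_to_bp("chr1", gmap.bp_to_cm("chr1", pos))
    assert np.all(np.abs(back - pos) <= 1)


# ------------------------------------------------------------------ crossing


def test_f1_generation_has_exactly_half_source_ancestry():
    cfg = SimConfig(seed=12, n_backcross_generations=0,
                    n_maintenance_generations=0, **{k: v for k, v in TINY.items()
                                                    if "generations" not in k})
    pop = simulate(cfg)
    neo = [s for s in pop.ancestry if "neo" in s]
    for s in neo:
        h1, h2 = pop.ancestry[s]
        origins = {seg[2] for segs in h1.values() for seg in segs}
        origins2 = {seg[2] for segs in h2.values() for seg in segs}
        assert {"source"} in (origins, origins2) and {"counterpart"} in (origins, origins2)
    assert abs(pop.source_fraction(neo) - 0.5) < 1e-12


def test_backcross_ancestry_matches_halving_rule():
    """Mean unlinked source ancestry after g backcrosses ~ (1/2)^(g+1).

    Measured on the chromosome not carrying the causal locus: at this genome
    scale the selected segment extends many cM around the locus, so the whole
    carrier chromosome is excluded rather than a fixed +-2 cM window.
    """
    vals = []
    for rep in range(20):
        cfg = SimConfig(seed=1000 + rep, n_groups=1, n_chromosomes=2,
                        n_sites_per_chromosome=300, n_source=4, n_counterpart=8,
                        n_neo=6, breeding_pool_size=12,
                        n_backcross_generations=4, n_maintenance_generations=2)
        pop = simulate(cfg)
        neo = [s for s in pop.ancestry if "neo" in s]
        vals.append(pop.source_fraction(neo, exclude_chroms=("chr1",)))
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 0.5**5) <= 3 * se


def test_causal_locus_carried_by_all_neo_bantams(demo_pop):
    gm = demo_pop.to_genotype_matrix()
    for g, (chrom, pos) in demo_pop.causal_loci.items():
        row = np.flatnonzero(
            (gm.sites["chrom"] == chrom).to_numpy() & (gm.sites["pos"] == pos).to_numpy()
        )[0]
        neo = demo_pop.samples[
            (demo_pop.samples["group"] == g) & (demo_pop.samples["role"] == "neo_bantam")
        ]["sample_id"]
        idx = [gm.samples.index(s) for s in neo]
        assert (gm.dosages[row, idx] >= 1).all()


def test_causal_carrier_phenotype_assignment(demo_pop):
    roles = demo_pop.samples
    assert (roles.loc[roles["role"] == "neo_bantam", "size_class"] == "bantam").all()
    assert (roles.loc[roles["role"] == "counterpart", "size_class"] == "normal").all()


def test_ancestry_segments_tile_chromosomes(demo_pop):
    L = demo_pop.config.chromosome_length_bp
    for s, haps in list(demo_pop.ancestry.items())[:10]:
        for segs in haps:
            for chrom, seglist in segs.items():
                assert seglist[0][0] == 0
                assert seglist[-1][1] == L
                for (s0, e0, _), (s1, e1, _) in zip(seglist, seglist[1:]):
                    assert e0 == s1 and s0 < e0
                assert sum(e - s for s, e, _ in seglist) == L


def test_simulation_is_bit_reproducible():
    a = simulate(SimConfig(seed=77, **TINY))
    b = simulate(SimConfig(seed=77, **TINY))
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert a.samples.equals(b.samples)
    assert a.ancestry_frame().equals(b.ancestry_frame())


# --------------------------------------------------------------------- files


def test_write_outputs_round_trip(tmp_path):
    pop = simulate(SimConfig(seed=21, **TINY))
    paths = write_outputs(pop, tmp_path)
    gm = read_vcf(paths["vcf"])
    truth = pop.to_genotype_matrix()
    assert gm.phased
    assert np.array_equal(gm.dosages, truth.dosages)
    assert np.array_equal(gm.haplotypes, truth.haplotypes)
    assert list(gm.samples) == list(truth.samples)
    # VCF positions are 1-based; ancestry BED is 0-based half-open
    assert gm.sites["pos"].min() >= 1
    bed = pd.read_csv(paths["ancestry"], sep="\t", header=None)
    assert bed[1].min() == 0
    assert bed[2].max() == pop.config.chromosome_length_bp
    meta = pd.read_csv(paths["samples"], sep="\t")
    cfg = pop.config
    assert len(meta) == cfg.n_groups * (cfg.n_source + cfg.n_counterpart + cfg.n_neo)
    gmap = GeneticMap.read(paths["map"])
    assert gmap.chromosomes == cfg.chrom_names()
    assert (tmp_path / "genes.gff3").read_text().startswith("##gff-version 3")
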