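"""VCF parsing, multi-allelic splitting, the QC cascade, sex inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bantamscan.containers import MISSING, GenotypeMatrix
from bantamscan.variant_qc import (
    QcThresholds,
    apply_qc,
    infer_sex,
    read_vcf,
    split_record,
    write_vcf,
)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_toy_vcf(path, rows, n_samples=4, with_dp=True):
    samples = "\t".join(f"s{i+1}" for i in range(n_samples))
    body = "\n".join(rows)
    path.write_text(HEADER.format(samples=samples) + body + "\n")
    return path


# ---------------------------------------------------------------------- read


def test_read_vcf_parses_gt_phase_missing_and_depth(tmp_path):
    rows = [
        "chr1\t100\tv1\tA\tG\t50\t.\t.\tGT:DP\t0|1:10\t1|1:12\t0|0:9\t.|.:3",
        "chr1\t200\tv2\tA\tC\t50\t.\t.\tGT:DP\t0/1:10\t0/0:10\t./.:10\t1/1:10",
    ]
    gm = read_vcf(write_toy_vcf(tmp_path / "t.vcf", rows))
    assert gm.n_sites == 2 and gm.n_samples == 4
    assert list(gm.dosages[0]) == [1, 2, 0, MISSING]
    assert list(gm.dosages[1]) == [1, 0, MISSING, 2]
    assert not gm.phased  # second record unphased
    assert gm.depth[0, 0] == 10

    gm2 = read_vcf(write_toy_vcf(tmp_path / "p.vcf", [rows[0]]))
    assert gm2.phased and gm2.haplotypes is not None
    assert list(gm2.haplotypes[0]) == [0, 1, 1, 1, 0, 0, MISSING, MISSING]


@pytest.mark.parametrize(
    "pairs,expected",
    [
        # tri-allelic "1/2": one dose of each alt
        ([(1, 2)], {"G": [1], "T": [1]}),
        ([(0, 1), (2, 2), (0, 0)], {"G": [1, 0, 0], "T": [0, 2, 0]}),
        ([(-1, -1), (0, 2)], {"G": [MISSING, 0], "T": [MISSING, 1]}),
    ],
)
def test_split_multiallelic_recoding(pairs, expected):
    out = split_record("A", ["G", "T"], np.array(pairs))
    assert len(out) == 2
    for (alt, dos), (exp_alt, exp_dos) in zip(out, expected.items()):
        assert alt == exp_alt
        assert list(dos) == exp_dos


def test_biallelic_record_passes_through():
    out = split_record("A", ["G"], np.array([(0, 1), (1, 1)]))
    assert len(out) == 1
    assert list(out[0][1]) == [1, 2]


def test_multiallelic_split_in_vcf_reader(tmp_path):
    rows = ["chr1\t100\tv1\tA\tG,T\t50\t.\t.\tGT:DP\t1/2:9\t0/1:9\t2/2:9\t0/0:9"]
    gm = read_vcf(write_toy_vcf(tmp_path / "m.vcf", rows))
    assert gm.n_sites == 2
    assert list(gm.sites["alt"]) == ["G", "T"]
    assert list(gm.sites["site_id"]) == ["v1_alt1", "v1_alt2"]
    assert list(gm.dosages[0]) == [1, 1, 0, 0]
    assert list(gm.dosages[1]) == [1, 0, 2, 0]


@given(
    pairs=st.lists(
        st.tuples(st.integers(-1, 3), st.integers(-1, 3)), min_size=1, max_size=8
    )
)
@settings(max_examples=50, deadline=None)
def test_split_dosage_sum_never_exceeds_ploidy(pairs):
    out = split_record("A", ["C", "G", "T"], np.array(pairs))
    total = np.zeros(len(pairs))
    for _, dos in out:
        d = np.asarray(dos, dtype=float)
        d[d == MISSING] = np.nan
        total += d
    assert np.all((total <= 2) | np.isnan(total))


# ------------------------------------------------------------------------ QC


def qc_fixture_vcf(tmp_path):
    """Seven sites, five of which each violate exactly one QC rule.

    A: site quality 5 (quality rule). B: 2/10 genotypes missing -> call rate
    0.8, not > 0.8 (call-rate rule). C: one genotype with depth 150, the
    rest without DP -> site mean depth 150 (mean-depth rule; only the one
    deep genotype is additionally masked, call rate stays 0.9). D: every
    genotype depth 2 -> all masked -> post-masking call rate 0
    (genotype-depth rule). E: no alt allele -> MAF 0 (MAF rule).
    F: exactly one het in 10 samples -> MAF 0.05, boundary retained.
    G: clean.
    """
    n = 10

    def row(pos, vid, qual, gts):
        return f"chr1\t{pos}\t{vid}\tA\tG\t{qual}\t.\t.\tGT:DP\t" + "\t".join(gts)

    het_plus = ["0/1:10"] * 5 + ["1/1:10"] * 5  # common variant
    rows = [
        row(100, "A", 5, het_plus),
        row(200, "B", 50, ["./.:10", "./.:10"] + ["0/1:10"] * 8),
        row(300, "C", 50, ["0/1:150"] + ["0/1:."] * 9),
        row(400, "D", 50, ["0/1:2"] * 10),
        row(500, "E", 50, ["0/0:10"] * 10),
        row(600, "F", 50, ["0/1:10"] + ["0/0:10"] * 9),
        row(700, "G", 50, het_plus),
    ]
    return write_toy_vcf(tmp_path / "qc.vcf", rows, n_samples=n)


def test_qc_cascade_per_rule_counts(tmp_path):
    gm = read_vcf(qc_fixture_vcf(tmp_path))
    filtered, report = apply_qc(gm)
    assert report.removed == {
        "quality": 1,
        "call_rate": 1,
        "genotype_depth": 1,
        "mean_depth": 1,
        "maf": 1,
    }
    assert report.n_pass == 2
    assert list(filtered.sites["site_id"]) == ["F", "G"]  # MAF 0.05 boundary kept


def test_qc_masks_genotypes_before_call_rate(tmp_path):
    gm = read_vcf(qc_fixture_vcf(tmp_path))
    filtered, report = apply_qc(gm)
    assert report.genotypes_masked == 11  # all of site D plus C's deep genotype


def test_qc_is_idempotent(tmp_path):
    gm = read_vcf(qc_fixture_vcf(tmp_path))
    once, _ = apply_qc(gm)
    twice, rep2 = apply_qc(once)
    assert np.array_equal(once.dosages, twice.dosages)
    assert rep2.n_pass == once.n_sites
    assert sum(rep2.removed.values()) == 0


def test_qc_survivors_monotone_in_threshold_strictness(tmp_path):
    gm = read_vcf(qc_fixture_vcf(tmp_path))
    base = apply_qc(gm, QcThresholds())[1].n_pass
    for stricter in [
        QcThresholds(min_site_quality=60),
        QcThresholds(min_call_rate=0.95),
        QcThresholds(site_mean_depth=(3, 9)),
        QcThresholds(genotype_depth=(11, 100)),
        QcThresholds(min_maf=0.3),
    ]:
        assert apply_qc(gm, stricter)[1].n_pass <= base


def test_qc_without_depth_matrix_skips_depth_rules(tmp_path):
    rows = ["chr1\t100\tv1\tA\tG\t50\t.\t.\tGT\t" + "\t".join(["0/1"] * 4)]
    samples = "\t".join(f"s{i+1}" for i in range(4))
    header = HEADER.format(samples=samples).replace(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n', ""
    )
    path = tmp_path / "nodp.vcf"
    path.write_text(header + rows[0] + "\n")
    gm = read_vcf(path)
    filtered, report = apply_qc(gm)
    assert report.n_pass == 1 and report.genotypes_masked == 0


def test_qc_all_sites_removed_signalled(tmp_path):
    rows = ["chr1\t100\tv1\tA\tG\t1\t.\t.\tGT:DP\t0/1:10\t0/0:10\t1/1:10\t0/1:10"]
    gm = read_vcf(write_toy_vcf(tmp_path / "e.vcf", rows))
    filtered, report = apply_qc(gm)
    assert report.n_pass == 0 and filtered.n_sites == 0


def test_write_vcf_round_trip(tmp_path):
    gm = read_vcf(qc_fixture_vcf(tmp_path))
    out = tmp_path / "rt.vcf"
    write_vcf(gm, out)
    back = read_vcf(out)
    assert np.array_equal(back.dosages, gm.dosages)
    assert np.array_equal(back.depth, gm.depth)


# ----------------------------------------------------------------------- sex


def test_sex_inference_from_coverage_ratio():
    z = np.array([10.0, 10.0, 10.0])
    w = np.array([0.0, 9.5, 3.0])  # ratio 0, 0.95, exactly at threshold
    out = infer_sex(z, w, threshold=0.3)
    assert list(out) == ["ZZ_male", "ZW_female", "ZW_female"]


def test_sex_inference_rejects_zero_z_coverage():
    with pytest.raises(ValueError):
        infer_sex(np.array([0.0]), np.array([1.0]))
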