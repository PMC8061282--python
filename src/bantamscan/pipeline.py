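"""End-to-end orchestration: simulate -> qc -> structure -> per-group GWAS ->
meta-analysis -> F_ST / rIBD -> lead-variant haplotypes -> annotation.

One flat YAML config drives everything; a manifest records the seed, the
per-stage parameters (as a config hash) and output checksums, and completed
stages are skipped on re-runs with an unchanged config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import gwas, haplo, introgression, meta, relatedness, simdata, variant_qc
from .containers import read_sample_table
from .genmap import GeneticMap

log = logging.getLogger("bantamscan")

STAGES = ["simulate", "qc", "structure", "gwas", "meta", "fst", "ribd", "haplo", "annotate"]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 1
    # either simulate... or point at existing inputs
    simulate: dict = field(default_factory=dict)
    vcf: str | None = None
    samples: str | None = None
    genetic_map: str | None = None
    genes: str | None = None
    qc: dict = field(default_factory=dict)
    gwas_mode: str = "null"
    threshold: float = gwas.GWAS_THRESHOLD
    window_bp: int = introgression.WINDOW_BP
    min_length_cm: float = 0.03
    flank_bp: int = 1000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stage runner with manifest-based resume."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
        if self.manifest.get("config_hash") != config.config_hash():
            log.info("config changed; previous stage results invalidated")
            self.manifest = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
        handler = logging.FileHandler(self.outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    # -------------------------------------------------------------- plumbing

    def _done(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry:
            return False
        return all(Path(p).exists() for p in entry["outputs"])

    def _record(self, stage: str, outputs: list[Path], params: dict | None = None) -> None:
        self.manifest["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "checksums": {str(p): _sha256(Path(p)) for p in outputs},
            "params": params or {},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, default=str))
        log.info("stage %s: wrote %d outputs", stage, len(outputs))

    def _inputs(self) -> tuple[Path, Path, Path, Path]:
        sim = self.outdir / "sim"
        vcf = Path(self.cfg.vcf) if self.cfg.vcf else sim / "panel.vcf"
        samples = Path(self.cfg.samples) if self.cfg.samples else sim / "samples.tsv"
        gmap = Path(self.cfg.genetic_map) if self.cfg.genetic_map else sim / "genetic_map.tsv"
        genes = Path(self.cfg.genes) if self.cfg.genes else sim / "genes.gff3"
        return vcf, samples, gmap, genes

    # ---------------------------------------------------------------- stages

    def stage_simulate(self) -> None:
        if self.cfg.vcf:
            log.info("simulate: external VCF supplied, skipping")
            return
        if self._done("simulate"):
            log.info("simulate: up to date")
            return
        sim_kwargs = dict(self.cfg.simulate)
        sim_kwargs.setdefault("seed", self.cfg.seed)
        config = simdata.SimConfig(**sim_kwargs)
        pop = simdata.simulate(config)
        paths = simdata.write_outputs(pop, self.outdir / "sim")
        self._record("simulate", list(paths.values()), {"seed": config.seed})

    def stage_qc(self) -> None:
        if self._done("qc"):
            return
        vcf, samples_path, _, _ = self._inputs()
        if not samples_path.exists():
            raise FileNotFoundError(
                f"qc stage: sample metadata file {samples_path} is missing"
            )
        gm = variant_qc.read_vcf(vcf)
        thresholds = variant_qc.QcThresholds(**self.cfg.qc)
        filtered, report = variant_qc.apply_qc(gm, thresholds)
        out_vcf = self.outdir / "filtered.vcf"
        out_rep = self.outdir / "qc_report.tsv"
        variant_qc.write_vcf(filtered, out_vcf)
        report.to_frame().to_csv(out_rep, sep="\t", index=False)
        self._record("qc", [out_vcf, out_rep])

    def _load(self) -> tuple:
        vcf, samples_path, gmap_path, _ = self._inputs()
        gm = variant_qc.read_vcf(self.outdir / "filtered.vcf")
        samples = read_sample_table(samples_path)
        gmap = GeneticMap.read(gmap_path)
        return gm, samples, gmap

    def stage_structure(self) -> None:
        if self._done("structure"):
            return
        gm, samples, _ = self._load()
        sim, dm = relatedness.ibs_matrix(gm)
        res = relatedness.pca(gm, n_components=min(10, gm.n_samples))
        tree = relatedness.nj_tree(dm)
        out = [
            self.outdir / "ibs_distance.tsv",
            self.outdir / "pca.tsv",
            self.outdir / "nj_tree.nwk",
        ]
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(out[0], sep="\t")
        res.to_frame().to_csv(out[1], sep="\t", index=False)
        relatedness.write_newick(tree, out[2])
        self._record("structure", out)

    def stage_gwas(self) -> None:
        if self._done("gwas"):
            return
        gm, samples, _ = self._load()
        out = []
        for g in sorted(samples["group"].unique()):
            scan, summary = gwas.run_group_scan(
                gm, samples, int(g), mode=self.cfg.gwas_mode, threshold=self.cfg.threshold
            )
            p = self.outdir / f"gwas_group{g}.tsv"
            scan.to_csv(p, sep="\t", index=False)
            (self.outdir / f"gwas_group{g}.summary.json").write_text(
                json.dumps(
                    {
                        "lambda_gc": summary.lambda_gc,
                        "n_significant": summary.n_significant,
                        "threshold": summary.threshold,
                        "n_variants": summary.n_variants,
                    },
                    indent=2,
                )
            )
            out += [p, self.outdir / f"gwas_group{g}.summary.json"]
        # pooled comparison scan
        pooled, psum = gwas.run_group_scan(
            gm, samples, None, mode=self.cfg.gwas_mode, threshold=self.cfg.threshold
        )
        p = self.outdir / "gwas_pooled.tsv"
        pooled.to_csv(p, sep="\t", index=False)
        out.append(p)
        self._record("gwas", out)

    def stage_meta(self) -> None:
        if self._done("meta"):
            return
        _, samples, _ = self._load()
        scans = [
            pd.read_csv(self.outdir / f"gwas_group{g}.tsv", sep="\t")
            for g in sorted(samples["group"].unique())
        ]
        table, summary = meta.run_meta(scans, threshold=self.cfg.threshold)
        p = self.outdir / "meta.tsv"
        table.to_csv(p, sep="\t", index=False)
        s = self.outdir / "meta.summary.json"
        s.write_text(json.dumps(summary, indent=2))
        self._record("meta", [p, s])

    def stage_fst(self) -> None:
        if self._done("fst"):
            return
        gm, samples, gmap = self._load()
        lengths = {c: gmap.length_bp(c) for c in gmap.chromosomes}
        out = []
        for g in sorted(samples["group"].unique()):
            grp = samples[samples["group"] == g]
            cohorts = {
                role: list(grp.loc[grp["role"] == role, "sample_id"])
                for role in ("source", "neo_bantam", "counterpart")
            }
            for other in ("source", "counterpart"):
                track = introgression.fst_scan(
                    gm, cohorts["neo_bantam"], cohorts[other], self.cfg.window_bp, lengths
                )
                p = self.outdir / f"fst_group{g}_neo_vs_{other}.tsv"
                track.to_csv(p, sep="\t", index=False)
                out.append(p)
        self._record("fst", out)

    def stage_ribd(self) -> None:
        if self._done("ribd"):
            return
        gm, samples, gmap = self._load()
        lengths = {c: gmap.length_bp(c) for c in gmap.chromosomes}
        out = []
        for g in sorted(samples["group"].unique()):
            grp = samples[samples["group"] == g]
            ids = {
                role: list(grp.loc[grp["role"] == role, "sample_id"])
                for role in ("source", "neo_bantam", "counterpart")
            }
            segs = pd.concat(
                [
                    introgression.detect_ibd(
                        gm, ids["source"], ids["neo_bantam"], gmap, self.cfg.min_length_cm
                    ),
                    introgression.detect_ibd(
                        gm, ids["counterpart"], ids["neo_bantam"], gmap, self.cfg.min_length_cm
                    ),
                ],
                ignore_index=True,
            )
            seg_path = self.outdir / f"ibd_group{g}.tsv"
            introgression.write_ibd_file(segs, seg_path)
            track = introgression.ribd_scan(segs, samples, int(g), self.cfg.window_bp, lengths)
            p = self.outdir / f"ribd_group{g}.tsv"
            track.to_csv(p, sep="\t", index=False)
            out += [seg_path, p]
        self._record("ribd", out)

    def stage_haplo(self) -> None:
        if self._done("haplo"):
            return
        gm, samples, _ = self._load()
        meta_table = pd.read_csv(self.outdir / "meta.tsv", sep="\t")
        finite = meta_table[meta_table["p"].notna()]
        if finite.empty:
            log.warning("haplo: no scored variants, skipping")
            self._record("haplo", [])
            return
        lead = finite.loc[finite["p"].idxmin()]
        out = []
        if gm.phased:
            block = haplo.extract_block(
                gm, str(lead["chrom"]), int(lead["pos"]), self.cfg.flank_bp, samples
            )
            tree = haplo.block_tree(block)
            prof = haplo.ld_profile(block)
            out = [
                self.outdir / "lead_block_tree.nwk",
                self.outdir / "lead_block_ld.tsv",
            ]
            relatedness.write_newick(tree, out[0])
            prof.to_csv(out[1], sep="\t", index=False)
        sig_mask = (meta_table["p"].notna() & (meta_table["p"] <= self.cfg.threshold)).to_numpy()
        if sig_mask.any():
            key = gm.sites.merge(
                meta_table.loc[sig_mask, ["chrom", "pos"]].drop_duplicates(),
                on=["chrom", "pos"],
                how="inner",
            )
            mask = gm.sites.set_index(["chrom", "pos"]).index.isin(
                key.set_index(["chrom", "pos"]).index
            )
            coords, tree = haplo.significant_variant_view(gm, mask, samples)
            p1 = self.outdir / "significant_pca.tsv"
            p2 = self.outdir / "significant_tree.nwk"
            coords.to_frame().to_csv(p1, sep="\t", index=False)
            relatedness.write_newick(tree, p2)
            out += [p1, p2]
        self._record("haplo", out)

    def stage_annotate(self) -> None:
        if self._done("annotate"):
            return
        gm, samples, _ = self._load()
        _, _, _, genes_path = self._inputs()
        genes = ann.read_gene_models(genes_path)
        groups = sorted(samples["group"].unique())
        sets: dict[str, set] = {}
        gene_sets: dict[str, set] = {}
        frames = {
            f"group{g}": pd.read_csv(self.outdir / f"gwas_group{g}.tsv", sep="\t")
            for g in groups
        }
        frames["meta"] = pd.read_csv(self.outdir / "meta.tsv", sep="\t")
        assigned_all = []
        for name, df in frames.items():
            sig = df[df["p"].notna() & (df["p"] <= self.cfg.threshold)]
            sets[name] = set(zip(sig["chrom"], sig["pos"]))
            if len(sig):
                assigned = ann.assign_variants(sig, genes, self.cfg.flank_bp)
                hit = assigned[~assigned["intergenic"]]
                gene_sets[name] = set(hit["gene_id"])
                assigned["analysis"] = name
                assigned_all.append(assigned)
            else:
                gene_sets[name] = set()
        out = [self.outdir / "assignments.tsv", self.outdir / "overlap_variants.tsv",
               self.outdir / "overlap_genes.tsv"]
        (pd.concat(assigned_all, ignore_index=True) if assigned_all else pd.DataFrame(
            columns=["chrom", "pos", "gene_id", "name", "intergenic", "analysis"]
        )).to_csv(out[0], sep="\t", index=False)
        ann.overlap_sets(sets).membership.to_csv(out[1], sep="\t")
        ann.overlap_sets(gene_sets).membership.to_csv(out[2], sep="\t")
        self._record("annotate", out)

    # ------------------------------------------------------------------ run

    def run(self, stages: list[str] | None = None) -> Path:
        for stage in stages or STAGES:
            fn = getattr(self, f"stage_{stage}")
            try:
                fn()
            except Exception as exc:
                log.error("stage %s failed; downstream stages not run", stage)
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        return self.outdir


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run (or resume) the full pipeline; returns the artifact directory."""
    return PipelineRun(config).run(stages)
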