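"""Forward simulation of the bantamization crossbreeding design.

The generator emulates how neo-bantam chicken breeds were created: a
normal-sized indigenous breed was crossed once with a true-bantam source
breed, the hybrids were repeatedly backcrossed to the normal-sized breed
while breeders kept only dwarf offspring, and the resulting neo-bantam line
was then maintained as a closed breed. Selection acts on a single major
causal locus per group; two of the default three groups share the same
causal locus, the third carries a private one, reproducing the heterogeneity
structure seen across real bantam groups.

Founder breeds are drawn from a Balding-Nichols model: every site has an
ancestral frequency p from a configurable Beta distribution, and each breed's
frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) for a per-breed drift parameter F.
Breeding parents are drawn from the sampled founder cohorts (breeds are small
closed populations), which is what creates realistic identity-by-descent
sharing between neo-bantams and both parental cohorts. The causal allele is
planted on a swept source-breed haplotype, mirroring the near-fixed
associated haplotypes observed in true bantam breeds.

Meiosis follows the Haldane model: crossover counts are Poisson in map
length, crossover positions uniform in cM, no interference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, write_sample_table
from .genmap import GeneticMap

__all__ = [
    "CausalLocus",
    "SimConfig",
    "FounderPanel",
    "Population",
    "generate_founders",
    "plant_causal_locus",
    "recombine",
    "simulate_cross",
    "simulate",
    "write_outputs",
]

SOURCE = "source"
COUNTERPART = "counterpart"


@dataclass(frozen=True)
class CausalLocus:
    """A causal position and the set of groups whose source breeds carry it."""

    chrom: str
    pos: int
    groups: tuple[int, ...]


@dataclass
class SimConfig:
    """Parameters of the bantamization simulation.

    Sample sizes are per group; the phenotyped panel per group is
    ``n_source`` true bantams + ``n_neo`` neo-bantams (cases) against
    ``n_counterpart`` normal-sized birds (controls).
    """

    seed: int
    n_groups: int = 3
    n_source: int = 5
    n_counterpart: int = 15
    n_neo: int = 10
    n_backcross_generations: int = 4
    #: closed-breed generations after the last backcross; recombination during
    #: maintenance breaks up the introgressed segment around the causal locus
    n_maintenance_generations: int = 8
    causal_loci: list[CausalLocus] | None = None
    selection_mode: str = "homozygote_preferred"  # or "carrier"
    n_chromosomes: int = 4
    chromosome_length_bp: int = 8_000_000
    n_sites_per_chromosome: int = 1500
    ancestral_freq_distribution: tuple[float, float] = (1.0, 1.0)
    breed_divergence_F: float = 0.2
    recombination_rate: float = 3.0  # cM per Mb
    phenotype_model: str = "causal_carrier"  # or "liability"
    liability_effect: float = 2.0
    liability_threshold: float = 1.0
    source_freq: float = 1.0
    counterpart_freq: float = 0.0
    sweep_radius_bp: int = 50_000
    breeding_pool_size: int = 24

    def __post_init__(self) -> None:
        counts = (
            self.n_groups,
            self.n_source,
            self.n_counterpart,
            self.n_neo,
            self.n_chromosomes,
            self.chromosome_length_bp,
            self.n_sites_per_chromosome,
            self.breeding_pool_size,
        )
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all counts in SimConfig must be positive")
        if self.n_backcross_generations < 0 or self.n_maintenance_generations < 0:
            raise ValueError("generation counts must be non-negative")
        if not 0.0 <= self.breed_divergence_F < 1.0:
            raise ValueError("breed_divergence_F must lie in [0, 1)")
        if self.selection_mode not in ("carrier", "homozygote_preferred"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.phenotype_model not in ("causal_carrier", "liability"):
            raise ValueError(f"unknown phenotype_model {self.phenotype_model!r}")
        if not (0.0 <= self.source_freq <= 1.0 and 0.0 <= self.counterpart_freq <= 1.0):
            raise ValueError("causal allele frequencies must lie in [0, 1]")
        for locus in self.causal_loci or ():
            if not 1 <= locus.pos <= self.chromosome_length_bp:
                raise ValueError(f"causal position {locus.pos} outside chromosome")
            if any(g < 1 or g > self.n_groups for g in locus.groups):
                raise ValueError("causal locus assigned to unknown group")

    # ------------------------------------------------------------- helpers

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length_bp for c in self.chrom_names()}

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.constant_rate(self.chrom_lengths(), self.recombination_rate)

    def default_causal_loci(self) -> list[CausalLocus]:
        """Groups 1 and 2 share a locus; every further group gets a private one."""
        chroms = self.chrom_names()
        mid = self.chromosome_length_bp // 2
        loci: list[CausalLocus] = []
        if self.n_groups == 1:
            return [CausalLocus(chroms[0], mid, (1,))]
        loci.append(CausalLocus(chroms[0], mid, (1, 2)))
        for g in range(3, self.n_groups + 1):
            chrom = chroms[(g - 2) % len(chroms)]
            # offset private loci so they never collide with the shared one
            pos = mid if chrom != chroms[0] else mid + (g - 1) * 1_000_000
            loci.append(CausalLocus(chrom, min(pos, self.chromosome_length_bp - 1), (g,)))
        return loci

    def breeds(self) -> list[str]:
        out = []
        for g in range(1, self.n_groups + 1):
            out += [f"group{g}_{SOURCE}", f"group{g}_{COUNTERPART}"]
        return out


# ===================================================================== founders


@dataclass
class FounderPanel:
    """Founder breed frequencies and sampled founder haplotype cohorts."""

    config: SimConfig
    sites: pd.DataFrame  # chrom, pos, ref, alt, qual, site_id
    gmap: GeneticMap
    breed_freqs: dict[str, np.ndarray]
    cohorts: dict[str, np.ndarray]  # (n_sites, 2 * n_individuals) int8
    causal_sites: dict[int, int] = field(default_factory=dict)  # group -> site row

    def site_index(self, chrom: str, pos: int) -> int | None:
        hit = np.flatnonzero(
            (self.sites["chrom"] == chrom).to_numpy()
            & (self.sites["pos"] == pos).to_numpy()
        )
        return int(hit[0]) if hit.size else None


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct 1-based positions, sorted."""
    got: np.ndarray = np.empty(0, dtype=np.int64)
    while got.size < n:
        cand = rng.integers(1, length + 1, size=2 * n)
        got = np.unique(np.concatenate([got, cand]))
    return np.sort(rng.choice(got, size=n, replace=False))


def generate_founders(config: SimConfig, rng: np.random.Generator | None = None) -> FounderPanel:
    """Draw founder breeds under the Balding-Nichols model.

    Every breed's per-site allele frequency is a Beta draw around a shared
    ancestral frequency; founder haplotype alleles are then independent
    Bernoulli draws at the breed frequency (all founders phased by
    construction). ``F = 0`` degenerates to all breeds sharing the ancestral
    frequency.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chroms = config.chrom_names()
    rows = []
    for chrom in chroms:
        for pos in _draw_positions(rng, config.n_sites_per_chromosome, config.chromosome_length_bp):
            rows.append((chrom, int(pos)))
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    sites["ref"] = "A"
    sites["alt"] = "G"
    sites["qual"] = 100.0
    sites["site_id"] = sites["chrom"] + "_" + sites["pos"].astype(str)

    a, b = config.ancestral_freq_distribution
    p = rng.beta(a, b, size=len(sites))
    p = np.clip(p, 1e-9, 1.0 - 1e-9)

    F = config.breed_divergence_F
    breed_freqs: dict[str, np.ndarray] = {}
    cohorts: dict[str, np.ndarray] = {}
    for breed in config.breeds():
        if F == 0.0:
            q = p.copy()
        else:
            scale = (1.0 - F) / F
            q = rng.beta(p * scale, (1.0 - p) * scale)
        breed_freqs[breed] = q
        n_ind = config.n_source if breed.endswith(SOURCE) else config.n_counterpart
        haps = (rng.random((len(sites), 2 * n_ind)) < q[:, None]).astype(np.int8)
        cohorts[breed] = haps
    return FounderPanel(config, sites, config.genetic_map(), breed_freqs, cohorts)


def plant_causal_locus(
    panel: FounderPanel,
    locus: CausalLocus,
    source_freq: float | None = None,
    counterpart_freq: float | None = None,
    sweep_radius_bp: int | None = None,
    rng: np.random.Generator | None = None,
) -> FounderPanel:
    """Plant the causal allele (and its swept haplotype) in founder breeds.

    For every group sharing the locus, source-breed haplotypes carry the
    causal allele at ``source_freq`` and counterpart haplotypes at
    ``counterpart_freq``. Carrier source haplotypes are additionally given a
    common breed-specific haplotype over ``pos +- sweep_radius_bp``,
    emulating the swept haplotype the causal variant rides on in a true
    bantam breed. Groups sharing a locus share position and allele; the
    swept background remains breed-specific.
    """
    cfg = panel.config
    rng = np.random.default_rng(cfg.seed + 104729) if rng is None else rng
    sf = cfg.source_freq if source_freq is None else source_freq
    cf = cfg.counterpart_freq if counterpart_freq is None else counterpart_freq
    radius = cfg.sweep_radius_bp if sweep_radius_bp is None else sweep_radius_bp
    if not (0.0 <= sf <= 1.0 and 0.0 <= cf <= 1.0):
        raise ValueError("causal allele frequencies must lie in [0, 1]")

    idx = panel.site_index(locus.chrom, locus.pos)
    if idx is None:
        idx = _insert_site(panel, locus.chrom, locus.pos, rng)

    chrom_mask = (panel.sites["chrom"] == locus.chrom).to_numpy()
    near = chrom_mask & (np.abs(panel.sites["pos"].to_numpy() - locus.pos) <= radius)
    sweep_rows = np.flatnonzero(near)

    for g in locus.groups:
        src, cpt = f"group{g}_{SOURCE}", f"group{g}_{COUNTERPART}"
        panel.breed_freqs[src][idx] = sf
        panel.breed_freqs[cpt][idx] = cf
        src_haps = panel.cohorts[src]
        cpt_haps = panel.cohorts[cpt]
        src_haps[idx] = (rng.random(src_haps.shape[1]) < sf).astype(np.int8)
        cpt_haps[idx] = (rng.random(cpt_haps.shape[1]) < cf).astype(np.int8)
        # breed-specific swept haplotype carrying the causal allele
        sweep = (rng.random(sweep_rows.size) < panel.breed_freqs[src][sweep_rows]).astype(np.int8)
        sweep[sweep_rows == idx] = 1
        carriers = np.flatnonzero(src_haps[idx] == 1)
        for h in carriers:
            src_haps[sweep_rows, h] = sweep
        panel.causal_sites[g] = idx
    return panel


def _insert_site(panel: FounderPanel, chrom: str, pos: int, rng: np.random.Generator) -> int:
    """Insert a brand-new site, keeping positions sorted within chromosome."""
    cfg = panel.config
    sites = panel.sites
    chrom_rows = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
    if chrom_rows.size == 0:
        raise ValueError(f"unknown chromosome {chrom!r}")
    after = chrom_rows[sites["pos"].to_numpy()[chrom_rows] < pos]
    row = int(after[-1] + 1) if after.size else int(chrom_rows[0])
    new = pd.DataFrame(
        [(chrom, pos, "A", "G", 100.0, f"{chrom}_{pos}")], columns=sites.columns
    )
    panel.sites = pd.concat(
        [sites.iloc[:row], new, sites.iloc[row:]], ignore_index=True
    )
    # causal variants are modeled as standing ancestral variation (a moderate
    # ancestral frequency), so they usually segregate in every breed and
    # cross-group heterogeneity at the locus is testable
    p = 0.5
    F = cfg.breed_divergence_F
    for breed in cfg.breeds():
        q = p if F == 0.0 else float(rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F))
        panel.breed_freqs[breed] = np.insert(panel.breed_freqs[breed], row, q)
        haps = panel.cohorts[breed]
        newrow = (rng.random(haps.shape[1]) < q).astype(np.int8)
        panel.cohorts[breed] = np.insert(haps, row, newrow, axis=0)
    for g, i in panel.causal_sites.items():
        if i >= row:
            panel.causal_sites[g] = i + 1
    return row


# ====================================================================== meiosis


@dataclass
class Haplotype:
    """One gamete/haplotype: alleles over all sites plus true ancestry segments.

    ``segments[chrom]`` is a list of (start_bp, end_bp, origin) tuples,
    0-based half-open, tiling the chromosome.
    """

    alleles: np.ndarray
    segments: dict[str, list[tuple[int, int, str]]]


def _founder_haplotype(panel: FounderPanel, breed: str, col: int, origin: str) -> Haplotype:
    cfg = panel.config
    segs = {c: [(0, cfg.chromosome_length_bp, origin)] for c in cfg.chrom_names()}
    return Haplotype(panel.cohorts[breed][:, col].copy(), segs)


def _clip_segments(
    segs: list[tuple[int, int, str]], lo: int, hi: int
) -> list[tuple[int, int, str]]:
    out = []
    for s, e, o in segs:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2, o))
    return out


def _merge_segments(segs: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    merged: list[tuple[int, int, str]] = []
    for seg in segs:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


class _SiteLayout:
    """Per-chromosome views into the flat, sorted site table."""

    def __init__(self, sites: pd.DataFrame, gmap: GeneticMap):
        self.chroms: list[str] = list(dict.fromkeys(sites["chrom"]))
        self.slices: dict[str, slice] = {}
        self.pos: dict[str, np.ndarray] = {}
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy()
        for chrom in self.chroms:
            rows = np.flatnonzero(chrom_arr == chrom)
            self.slices[chrom] = slice(int(rows[0]), int(rows[-1]) + 1)
            self.pos[chrom] = pos_arr[self.slices[chrom]].astype(np.int64)
        self.gmap = gmap


def recombine(
    parent: tuple[Haplotype, Haplotype],
    layout: _SiteLayout,
    rng: np.random.Generator,
) -> Haplotype:
    """One meiosis under the Haldane (no-interference) model.

    Crossover counts per chromosome are Poisson in the chromosome's map
    length (Morgans); crossover positions are uniform in cM and mapped back
    to bp by inverse linear interpolation; the starting parental haplotype
    is chosen at random per chromosome.
    """
    hapA, hapB = parent
    alleles = np.empty_like(hapA.alleles)
    segments: dict[str, list[tuple[int, int, str]]] = {}
    for chrom in layout.chroms:
        L_cm = layout.gmap.length_cm(chrom)
        L_bp = layout.gmap.length_bp(chrom)
        # a 0-cM chromosome never recombines: the gamete is one parental
        # haplotype copied intact
        n_x = rng.poisson(L_cm / 100.0) if L_cm > 0 else 0
        if n_x:
            cuts_cm = np.sort(rng.uniform(0.0, L_cm, size=n_x))
            cuts_bp = np.asarray(layout.gmap.cm_to_bp(chrom, cuts_cm), dtype=np.int64)
            cuts_bp = np.unique(cuts_bp)
        else:
            cuts_bp = np.empty(0, dtype=np.int64)
        start = int(rng.integers(2))
        sl = layout.slices[chrom]
        pos = layout.pos[chrom]
        # which parental haplotype each site copies from
        which = (start + np.searchsorted(cuts_bp, pos, side="right")) % 2
        a = hapA.alleles[sl]
        b = hapB.alleles[sl]
        alleles[sl] = np.where(which == 0, a, b)
        bounds = np.concatenate([[0], cuts_bp, [L_bp]])
        segs: list[tuple[int, int, str]] = []
        for i in range(len(bounds) - 1):
            src = (hapA, hapB)[(start + i) % 2]
            segs += _clip_segments(src.segments[chrom], int(bounds[i]), int(bounds[i + 1]))
        segments[chrom] = _merge_segments(segs)
    return Haplotype(alleles, segments)


Individual = tuple[Haplotype, Haplotype]


def _dosage(ind: Individual, site: int) -> int:
    return int(ind[0].alleles[site]) + int(ind[1].alleles[site])


# ====================================================================== crossing


@dataclass
class Population:
    """Genotyped panel emitted by the simulator, with truth tracks."""

    config: SimConfig
    sites: pd.DataFrame
    gmap: GeneticMap
    samples: pd.DataFrame  # sample_id, breed, size_class, role, group
    haplotypes: np.ndarray  # (n_sites, 2 * n_samples) int8
    ancestry: dict[str, tuple[list, list]]  # sample -> (segments hap1, hap2)
    causal_loci: dict[int, tuple[str, int]]  # group -> (chrom, pos)

    def to_genotype_matrix(self) -> GenotypeMatrix:
        n = len(self.samples)
        dos = (
            self.haplotypes[:, 0::2].astype(np.int8)
            + self.haplotypes[:, 1::2].astype(np.int8)
        )
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=list(self.samples["sample_id"]),
            dosages=dos,
            phased=True,
            haplotypes=self.haplotypes.copy(),
        )

    def ancestry_frame(self) -> pd.DataFrame:
        """Truth ancestry as a BED-style table (0-based half-open)."""
        rows = []
        for sample, haps in self.ancestry.items():
            for h, segs in enumerate(haps, start=1):
                for chrom, seglist in segs.items():
                    for s, e, o in seglist:
                        rows.append((chrom, s, e, sample, h, o))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "sample_id", "hap", "origin"]
        )

    def source_fraction(
        self, sample_ids: list[str] | None = None, exclude_chroms: tuple[str, ...] = ()
    ) -> float:
        """Mean fraction of genome (bp) with true bantam-source origin."""
        ids = sample_ids or list(self.ancestry)
        tot = src = 0
        for s in ids:
            for segs in self.ancestry[s]:
                for chrom, seglist in segs.items():
                    if chrom in exclude_chroms:
                        continue
                    for a, b, o in seglist:
                        tot += b - a
                        if o == SOURCE:
                            src += b - a
        return src / tot if tot else float("nan")


class SelectionExtinctionError(RuntimeError):
    """Raised when selection cannot produce enough carriers."""


def _accepts(dosage: int) -> bool:
    return dosage >= 1


def _breed_generation(
    make_offspring,
    causal_site: int,
    mode: str,
    pool_size: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """Produce one selected generation; deterministic and bounded."""
    want = 2 * pool_size if mode == "homozygote_preferred" else pool_size
    accepted: list[tuple[int, Individual]] = []
    attempts = 0
    limit = 400 * pool_size
    while len(accepted) < want and attempts < limit:
        attempts += 1
        child = make_offspring(rng)
        d = _dosage(child, causal_site)
        if _accepts(d):
            accepted.append((d, child))
    if len(accepted) < pool_size:
        raise SelectionExtinctionError("selection extinguished the carrier pool")
    if mode == "homozygote_preferred":
        order = sorted(range(len(accepted)), key=lambda i: (-accepted[i][0], i))
        accepted = [accepted[i] for i in order[:pool_size]]
    else:
        accepted = accepted[:pool_size]
    return [ind for _, ind in accepted]


def _simulate_group(
    panel: FounderPanel,
    layout: _SiteLayout,
    group: int,
    rng: np.random.Generator,
) -> tuple[list[Individual], list[Individual], list[Individual]]:
    """Return (source cohort, counterpart cohort, neo cohort) for one group."""
    cfg = panel.config
    src_breed, cpt_breed = f"group{group}_{SOURCE}", f"group{group}_{COUNTERPART}"
    causal = panel.causal_sites.get(group)
    if causal is None:
        raise ValueError(f"no causal locus planted for group {group}")

    def founder_ind(breed: str, i: int, origin: str) -> Individual:
        return (
            _founder_haplotype(panel, breed, 2 * i, origin),
            _founder_haplotype(panel, breed, 2 * i + 1, origin),
        )

    source_cohort = [founder_ind(src_breed, i, SOURCE) for i in range(cfg.n_source)]
    cpt_cohort = [founder_ind(cpt_breed, i, COUNTERPART) for i in range(cfg.n_counterpart)]

    def random_cpt(r: np.random.Generator) -> Individual:
        return cpt_cohort[int(r.integers(len(cpt_cohort)))]

    def cross(mother: Individual, father: Individual, r: np.random.Generator) -> Individual:
        return (recombine(mother, layout, r), recombine(father, layout, r))

    max_retries = 5
    for retry in range(max_retries):
        r = np.random.default_rng(rng.integers(2**31)) if retry else rng
        try:
            # F1: source x counterpart
            def f1_offspring(rr, _src=source_cohort):
                return cross(_src[int(rr.integers(len(_src)))], random_cpt(rr), rr)

            pool = _breed_generation(
                f1_offspring, causal, cfg.selection_mode, cfg.breeding_pool_size, r
            )
            # repeated backcrossing to the normal-sized breed
            for _ in range(cfg.n_backcross_generations):
                def bc_offspring(rr, _pool=pool):
                    return cross(_pool[int(rr.integers(len(_pool)))], random_cpt(rr), rr)

                pool = _breed_generation(
                    bc_offspring, causal, cfg.selection_mode, cfg.breeding_pool_size, r
                )
            # closed-breed maintenance of the neo-bantam line
            for _ in range(cfg.n_maintenance_generations):
                def mt_offspring(rr, _pool=pool):
                    i = int(rr.integers(len(_pool)))
                    j = int(rr.integers(len(_pool) - 1))
                    j = j + 1 if j >= i else j
                    return cross(_pool[i], _pool[j], rr)

                pool = _breed_generation(
                    mt_offspring, causal, cfg.selection_mode, cfg.breeding_pool_size, r
                )
            break
        except SelectionExtinctionError:
            if retry == max_retries - 1:
                raise
            warnings.warn(f"group {group}: carrier pool extinguished, retrying")
    neo_idx = rng.choice(len(pool), size=cfg.n_neo, replace=False)
    neo_cohort = [pool[int(i)] for i in neo_idx]
    return source_cohort, cpt_cohort, neo_cohort


def simulate_cross(
    config: SimConfig,
    panel: FounderPanel,
    gmap: GeneticMap | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Run the full crossbreeding design and assemble the genotyped panel."""
    rng = np.random.default_rng(config.seed + 15485863) if rng is None else rng
    gmap = panel.gmap if gmap is None else gmap
    layout = _SiteLayout(panel.sites, gmap)

    sample_rows = []
    hap_cols: list[np.ndarray] = []
    ancestry: dict[str, tuple] = {}
    causal_loci: dict[int, tuple[str, int]] = {}

    for g in range(1, config.n_groups + 1):
        causal_site = panel.causal_sites[g]
        causal_loci[g] = (
            str(panel.sites["chrom"].iloc[causal_site]),
            int(panel.sites["pos"].iloc[causal_site]),
        )
        src, cpt, neo = _simulate_group(panel, layout, g, rng)
        for role, tag, cohort in (
            (SOURCE, "src", src),
            (COUNTERPART, "cpt", cpt),
            ("neo_bantam", "neo", neo),
        ):
            for i, ind in enumerate(cohort):
                sid = f"g{g}_{tag}{i + 1}"
                dosage = _dosage(ind, causal_site)
                if config.phenotype_model == "causal_carrier":
                    bantam = dosage >= 1
                else:  # liability
                    liab = config.liability_effect * dosage + rng.standard_normal()
                    bantam = liab > config.liability_threshold
                sample_rows.append(
                    (
                        sid,
                        f"group{g}_{'neo' if role == 'neo_bantam' else role}",
                        "bantam" if bantam else "normal",
                        role,
                        g,
                    )
                )
                hap_cols += [ind[0].alleles, ind[1].alleles]
                ancestry[sid] = (ind[0].segments, ind[1].segments)

    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "breed", "size_class", "role", "group"]
    )
    haplotypes = np.column_stack(hap_cols).astype(np.int8)
    return Population(
        config=config,
        sites=panel.sites.copy(),
        gmap=gmap,
        samples=samples,
        haplotypes=haplotypes,
        ancestry=ancestry,
        causal_loci=causal_loci,
    )


def simulate(config: SimConfig) -> Population:
    """Founders -> planted causal loci -> crossbreeding, in one call."""
    rng = np.random.default_rng(config.seed)
    panel = generate_founders(config, rng)
    loci = config.causal_loci or config.default_causal_loci()
    for locus in loci:
        plant_causal_locus(panel, locus, rng=rng)
    return simulate_cross(config, panel, rng=rng)


# ======================================================================= output


def write_outputs(pop: Population, outdir: str | Path) -> dict[str, Path]:
    """Write phased VCF, sample metadata, genetic map, toy gene models and
    the truth ancestry track. Returns the paths keyed by artifact name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "panel.vcf",
        "samples": outdir / "samples.tsv",
        "map": outdir / "genetic_map.tsv",
        "genes": outdir / "genes.gff3",
        "ancestry": outdir / "ancestry.bed",
    }
    _write_vcf(pop, paths["vcf"])
    write_sample_table(pop.samples, paths["samples"])
    pop.gmap.write(paths["map"])
    _write_gff3(pop, paths["genes"])
    anc = pop.ancestry_frame()
    anc.to_csv(paths["ancestry"], sep="\t", index=False, header=False)
    return paths


def _write_vcf(pop: Population, path: Path) -> None:
    ids = list(pop.samples["sample_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bantamscan-simulate\n")
        for chrom, length in pop.config.chrom_lengths().items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        H = pop.haplotypes
        sites = pop.sites
        for i in range(len(sites)):
            gts = [f"{H[i, 2 * j]}|{H[i, 2 * j + 1]}" for j in range(len(ids))]
            fh.write(
                f"{sites['chrom'].iloc[i]}\t{sites['pos'].iloc[i]}\t{sites['site_id'].iloc[i]}"
                f"\t{sites['ref'].iloc[i]}\t{sites['alt'].iloc[i]}\t{sites['qual'].iloc[i]:g}"
                f"\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _write_gff3(pop: Population, path: Path) -> None:
    """Toy gene models: one growth gene over each causal locus plus a lattice
    of background genes, so annotation has both hits and misses."""
    cfg = pop.config
    lines = ["##gff-version 3"]
    for chrom, length in cfg.chrom_lengths().items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
    feats = []
    for g, (chrom, pos) in sorted(pop.causal_loci.items()):
        start = max(1, pos - 25_000)
        end = min(cfg.chromosome_length_bp, pos + 25_000)
        gid = f"BANTAM_G{g}"
        feats.append((chrom, start, end, gid, f"growth gene over group-{g} causal locus"))
    for ci, (chrom, length) in enumerate(cfg.chrom_lengths().items()):
        for k, s in enumerate(range(500_000, length - 20_000, 1_000_000)):
            feats.append((chrom, s, s + 20_000, f"BG{ci + 1}_{k + 1}", "background gene"))
    seen = set()
    for chrom, start, end, gid, note in sorted(feats):
        if gid in seen:
            continue
        seen.add(gid)
        lines.append(
            f"{chrom}\tbantamscan\tgene\t{start}\t{end}\t.\t+\t.\t"
            f"ID={gid};Name={gid};biotype=protein_coding"
        )
    Path(path).write_text("\n".join(lines) + "\n")
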