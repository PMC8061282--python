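# Methods

## The design being modeled

A "bantamized" (neo-bantam) breed is a miniature counterpart of a
normal-sized breed, created by one cross to a true-bantam donor breed,
g generations of backcrossing to the normal-sized breed with selection for
the dwarf phenotype, and closed-breed maintenance thereafter. Absent
selection, the expected donor-genome fraction after g backcrosses is
(1/2)^(g+1); selection pins a donor segment around each causal locus. Groups
of neo-bantam breeds that used the same donor share causal variation; groups
with different donors do not. The package's analyses are all ways of reading
this structure out of genotype data: group-stratified mixed-model GWAS for
the causal loci, meta-analysis with heterogeneity testing for cross-group
sharing, windowed F_ST and relative IBD for the local donor introgression,
and haplotype phylogenies for whether phenotype, not overall relatedness,
organizes the causal region.

## Statistical models

**Linear mixed model (per-group scan).** y = Wα + xβ + u + e with
u ~ N(0, σ²_g K), e ~ N(0, σ²_e I); y is the 0/1 size class treated as
quantitative, K the IBS similarity matrix of the scanned samples, W an
intercept (covariates optional). With λ = σ²_g/σ²_e and K = U S Uᵀ computed
once, the rotated model has diagonal covariance σ²_e·diag(λS + 1), so REML
is a 1-D problem in log λ: a 61-point grid on [10⁻⁵, 10⁵] followed by
bounded Brent refinement around the best grid point; ties (and flat
profiles) resolve to the smaller λ because the grid argmin takes the first
minimum. Eigenvalues of K are clamped at zero (with a warning when material).
By default each variant reuses the null-model λ (the standard approximation
for panels of this size); `mode="exact"` re-optimizes λ per variant. The
Wald statistic (β/se)² is referred to χ²₁; se comes from the
Frisch–Waugh-residualized GLS with σ̂² = RSS/(n−c−1).

Two numerical guards matter at simulation scale: the GLS residual sum of
squares is floored at 10⁻¹⁰ of the phenotype sum of squares, because a major
locus can separate a small case/control panel perfectly and se = 0 would
propagate infinite weights into the meta-analysis; and p-values are clamped
to the smallest positive float with the χ² statistic carried alongside, so
underflowing tests keep a usable ordering. Genomic control is
λ_GC = median(χ²)/0.4549364 (the χ²₁ median). Missing dosages are imputed to
the per-variant mean; monomorphic variants are emitted as NA with a reason.

**Meta-analysis.** Classical fixed-effects inverse-variance weighting:
w_i = 1/se²_i, β̂ = Σw_iβ_i/Σw_i, se = (Σw_i)^(−1/2), two-sided normal p.
Genomic control is applied per input study (se inflated by √λ_GC when
λ_GC > 1; never deflated), not to the combined statistic. Heterogeneity:
Q = Σw_i(β_i − β̂)² against χ² with k−1 df, I² = max(0, (Q−(k−1))/Q), and a
per-study direction string with "?" for missing. Studies are matched on
(chrom, pos) with allele alignment to the first study; swapped ref/alt flips
the sign, anything else is excluded and logged. Variants present in one
study are reported with k = 1 and no heterogeneity test, and are excluded
from the heterogeneity fraction of significant variants.

**Weir–Cockerham F_ST.** Two-population variance components a (among
populations), b (among individuals within populations) and c (within
individuals) from per-population sample sizes, allele frequencies and
observed heterozygote proportions, with the unequal-sample-size corrections
(n̄, n_c, p̄, s², h̄). Windows tile each chromosome as [k·w, (k+1)·w) in
0-based coordinates (w = 10 kb by default) and use the ratio-of-sums
estimator Σa/Σ(a+b+c) over informative sites — the weighted window
estimator, deliberately not the mean of per-site ratios. Windows without an
informative site are NA and excluded from means.

**IBD and rIBD.** Segments between phased haplotypes are maximal runs of
allele identity allowing at most `max_mismatches` (default 1) internal
mismatches, reported when their genetic length reaches `min_length_cm`;
runs never start or end on a mismatch. The detector is deterministic and
symmetric; externally detected segment files (tab-delimited: sample1, hap1,
sample2, hap2, chrom, start, end, score; 1-based inclusive coordinates) are
accepted interchangeably. For cohorts X and N, cIBD per window counts
haplotype *pairs* (one from each cohort) with at least one segment
overlapping the window — pair-counting bounds nIBD = cIBD/tIBD by 1, with
tIBD = 2|X|·2|N|; any overlap with a window counts. rIBD =
nIBD(source↔neo) − nIBD(counterpart↔neo); positive values mark donor
introgression.

**Trees and LD.** Neighbor joining is the Saitou–Nei agglomeration with the
Q-criterion minimized scanning the upper triangle in lexicographic order
(deterministic ties), negative branch lengths clamped at zero, and an
unrooted trifurcation at the root; on additive matrices it reproduces the
generating tree exactly, which the tests verify by enumerating every
topology with up to six leaves. LD is computed from phased haplotype
frequencies, r² = (p_AB − p_Ap_B)²/(p_A(1−p_A)p_B(1−p_B)); the "high LD"
reporting threshold is r² > 0.9.

**Sex inference.** The W/Z mean-coverage ratio with threshold 0.3 (≥ calls a
ZW female). The threshold is a configuration value; it sits in the gap of
the strongly bimodal ratio distribution (females ≈ 1, males ≈ 0).

## Quality control

Order of operations: (1) genotypes with depth outside [3, 100] are masked to
missing; (2) sites are dropped for quality ≤ 10, call rate ≤ 0.8 (recomputed
after masking), or mean depth outside [3, 100]; (3) sites with MAF < 0.05
(computed on non-missing alleles) are dropped. Quality and call-rate bounds
are strict, depth bounds inclusive, and MAF exactly 0.05 is retained. Site
mean depth uses the original depths of genotyped calls, so QC is idempotent.
A site that passes call rate before masking but fails after is attributed to
the genotype-depth rule, giving five distinct per-rule removal counts.
Multi-allelic records are split into one row per alternate allele (other
alternates count as the reference class; any missing allele makes the
genotype missing in every split row), each row keeping a distinct allele
identifier.

## The simulator

`SimConfig` defaults define the study conditions:

| parameter | default | why |
|---|---|---|
| groups | 3 (donors of groups 1+2 share the causal locus; group 3 private) | the observed sharing structure across bantam origins |
| samples per group | 5 source + 15 counterpart + 10 neo (15 cases / 15 controls) | small-breed panel scale, n ≈ 30 per group |
| backcross generations g | 4 | breeders' records do not fix g; 4 gives ~3% residual donor genome |
| maintenance generations | 8 | neo-bantam lines are closed breeds maintained for decades; recombination during maintenance shortens the selected donor segment so localization is meaningful at this genome scale |
| selection mode | homozygote-preferred carriers | phenotypic selection on a partially dominant major locus enriches homozygotes, matching the high associated-allele frequencies seen in real bantams |
| genome | 4 chromosomes × 8 Mb, 1,500 sites each | the selected segment (several cM) must remain a small fraction of the genome for genome-wide vs regional contrasts to exist |
| ancestral frequencies | Beta(1, 1) | uninformative spectrum |
| breed drift F | 0.2 | gives between-breed F_ST ≈ 0.2, the upper end of realistic breed differentiation |
| recombination | constant 3 cM/Mb | chicken-like genome-wide average; user map files accepted |
| causal allele | frequency 1.0 in the donor on a swept ±50 kb haplotype, 0.0 in the counterpart; ancestral frequency 0.5 elsewhere | the causal variant is standing variation riding a donor-breed sweep |

Founders follow the Balding–Nichols model: per site an ancestral frequency p,
per breed a Beta(p(1−F)/F, (1−p)(1−F)/F) draw, haplotype alleles independent
Bernoulli at the breed frequency. Two deliberate departures from the plain
model give breeds internal haplotype structure, without which no IBD signal
can exist: breeding parents are drawn from the *sampled founder cohorts*
(breeds are small closed populations, so the genotyped birds are relatives
of the crossbreeding ancestors), and the causal allele is planted on a
single swept haplotype shared by donor carriers. Meiosis is Haldane
(Poisson crossovers in map length, uniform in cM, no interference, random
starting haplotype); a 0-cM chromosome is transmitted intact. Selection is
truncation on causal genotype rather than phenotype — equivalent under the
carrier phenotype model. If selection empties the carrier pool the group is
re-drawn with a fresh substream up to five times before failing.

Outputs: phased VCF 4.2, sample table (id, breed, size class, role, group),
genetic map, toy GFF3 gene models over the causal loci plus background
genes, and the truth ancestry track as BED (0-based half-open). Seeded runs
are bit-reproducible.

**What the simulator does not emulate.** Linkage disequilibrium within
founder breeds away from the swept region (sites are exchangeable given the
breed frequencies), mutation, genotyping error and missingness (QC depth
rules are exercised by constructed fixtures instead), sex chromosomes,
overlapping generations, pedigree loops, and selection on a polygenic
background (a liability phenotype model exists but is off by default).
Passing the simulation-based tests therefore demonstrates that the inference
chain recovers planted truth under the crossbreeding design's genetic
structure — not that it is robust to sequencing artifacts or to polygenic
architectures.

## Scale-dependent analysis settings

The simulated marker density (one site per ~5.3 kb, ~0.016 cM) is ~70×
sparser than a whole-genome call set, and two settings scale with density:

- **IBD detection length.** On multi-million-variant panels a 0.03 cM
  minimum segment length is discriminative because unrelated haplotypes
  mismatch every few hundred bp. At the simulated density, random pairs
  produce match runs of ~0.12 cM, so 0.03 cM saturates cIBD. Simulation-
  scale analyses use `min_length_cm = 0.3` — the swept-haplotype scale
  (2 × 50 kb × 3 cM/Mb) and ~2.5× the background run length. The detector's
  own default stays 0.03 for dense data.
- **Regional windows.** rIBD recovery is scored on the 100-kb window
  centered on the causal locus. The regional F_ST contrast is measured over
  ±100 kb: inside the swept 100-kb core a fully fixed donor sweep can leave
  no informative site between neo-bantams and the donor, while the ring just
  outside stays polymorphic in both comparisons.

## Null-calibration experiment

The type-I-error check of the mixed-model scan is designed so that its
nominal χ²₁ reference actually applies: (i) the panel has two related
subpopulations at F = 0.05 — the differentiation level between a group's
case and control breeds, which are close relatives, not the F = 0.2 of
distant donors (with very strong structure the REML fit absorbs each
phenotype's chance alignment with the structure axis and the scan becomes
intentionally conservative); (ii) n = 800 birds, because exactly balanced
permutations of integer dosages make the Wald statistic discrete and
finite-sample conservative below that scale; (iii) the kinship is computed
from a marker subset disjoint from the tested variants — the array-subset
kinship practice — avoiding proximal contamination; (iv) 10,000 tests are
spread over 20 independent permutations so the exact binomial reference for
the type-I count, which presumes independent tests, is appropriate.

## Pipeline

`run-all` executes simulate → qc → structure → per-group gwas (+ pooled) →
meta → fst → ribd → haplo → annotate from one YAML config, logging to
console and `run.log`, and records a manifest (config hash, seed, per-stage
outputs and SHA-256 checksums). Re-running with an unchanged config skips
completed stages; changing the config invalidates them. A stage failure
aborts with the stage named; downstream outputs are not written.

## Known limitations

- The LMM treats a binary trait as quantitative (no liability-scale or
  logistic mixed model); with a major locus and small n, perfectly separated
  variants rely on the RSS floor for finite output.
- Identical genotype patterns (e.g., a drift-fixed site fully linked to the
  causal haplotype in a small bottlenecked pedigree) are statistically
  indistinguishable from the causal site; lead-variant localization can tie
  away from the locus in a minority of replicates.
- The IBD detector is an identity-run scanner, not a probabilistic model; it
  honors length/mismatch criteria but produces no LOD scores (the score
  column is the matching-site count), and overlapping maximal runs are all
  reported.
- Strand-ambiguity handling (A/T, C/G flips) is out of scope for allele
  alignment; the simulator emits none.
- PCA and IBS use pairwise-complete missing handling; a pair with zero
  overlapping loci is an error rather than an imputed value.
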