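# Methods

This note documents the statistical and algorithmic choices in
`gbmcontrast`, what the synthetic-data generator does and does not
emulate, and the numerical conventions, in the package's own words.

## Cohort model and identity conventions

The analysis compares groups of tumors defined by recurrence-free
survival: S (< 6 months), M (16–23), L (> 25). Exome-level operations
quantify over the *sequenced* samples only — in the emulated cohort 4
of 6 S patients and all 4 L patients have exomes, and the pipeline
restricts the manifest to samples that actually carry variant records
before any "all samples of the group" rule is applied. Transcriptome
operations use the full 13-sample manifest (6 S / 3 M / 4 L).

Variant identity is the key (chrom, pos, ref, alt) — sample-,
zygosity- and annotation-independent, so that "the same variant in
all samples" is a well-defined single event. Gene identity is the
annotated symbol; records without a gene annotation are kept in
burden totals but excluded from gene-level operations.

Two counting conventions coexist by design:

* **occurrence counts** for cohort-level burden (each sample's record
  counts once) — the scale on which the headline totals live;
* **distinct-key counts per group** for per-gene statistics — a
  variant shared by all four samples of a group is one variant *of
  the gene*. Hypermutation flagging (> 50 distinct variants per gene
  per group, strict) and the recurrent-gene rule (> 4 distinct
  variants, mutated in every group sample, absent from the other
  group) both use the distinct convention. Occurrence counts per
  gene are also computed and written for comparison.

"Deleterious" is an input annotation from the upstream caller, never
recomputed, with the convention deleterious ⊆ coding.

## Contingency tests

Every count contrast is a 2×2 table with the group's mutated-gene
count as margin. The default test is the Pearson chi-square without
continuity correction (df = 1, two-sided); this is the test that
reproduces the published p = 0.0005 on the hypermutation table
(35/12714 vs 9/11126 → p = 0.000485), where the Yates-corrected
statistic gives 0.00085. Yates and Fisher's exact (two-sided, via the
hypergeometric distribution) are available behind the `method` flag.
Tables with a zero margin are rejected as degenerate (the pipeline
skips them with an explicit reason rather than failing). The three
burden tests are reported with raw p-values; no multiple-testing
correction is applied across them.

## Differential expression

The DE engine is deliberately a simple, replaceable stand-in: the
package's contribution is the partition and integration logic, which
is engine-agnostic (externally computed tables can be imported via
TSV). Pairwise comparisons use Welch's *t* on log₂(FPKM + 1); the
three-group screen uses one-way ANOVA on the same transform; both are
followed by Benjamini–Hochberg FDR control with significance at
q < 0.05. "M vs rest" pools the S and L samples on one side; the two
separate pairwise comparisons are available as an alternative.

Degenerate genes — zero variance on both sides — are resolved
deterministically: p = 1 when the side means agree, p = 0 when they
differ. The comparison uses a per-row tolerance of 10⁻⁹·(scale + 1)
rather than exact zero, because means of bit-identical floating-point
values can differ by ~10⁻¹⁵ through summation rounding, which would
otherwise manufacture enormous t statistics from pure noise. This
rule is what makes recovery of noise-free planted signal exact; genes
with genuine within-group variance never reach it.

The Venn partition assigns each significant gene to one of the 7
regions of the three pairwise comparisons (S-L, S-M, M-L); region
counts sum to the union of the significant sets.

## Copy-number contrast

Coverage tracks are library-size normalized by scaling each track's
integer counts to a reference depth of 100 per bin (dividing by the
track total first, so multiplying a track by a constant is bit-exactly
neutral). Group tracks are the per-bin mean of the normalized member
tracks. The per-bin statistic is
log₂(test + c) − log₂(control + c) with pseudocount c = 0.5, computed
as a difference of logarithms so that swapping the two sides negates
the track bit-exactly, then median-centered per track so the modal
(diploid) copy state sits at zero — without centering, the mass of an
amplified region drags the genome-wide baseline down by its share of
the total.

Segments are called with a cut-off *c* and an SD band *b*
(tumor-vs-normal c = 1.0, group contrast c = 0.8, b = 0.5 — the
published parameterization "c ± 0.5 SD" is read as a cut-off with a
half-SD tolerance band):

1. a bin is an amplified (deleted) candidate when its log₂ ratio is
   ≥ c − b (≤ −(c − b));
2. single-bin gaps inside a same-sign candidate run are closed (one
   Poisson dropout must not split a segment);
3. maximal same-sign runs of ≥ `min_bins` (default 5) bins are
   retained when their within-run standard deviation is ≤ b — a
   stability filter against noisy spikes;
4. everything else is neutral, so segments tile the binned genome.

The band is essential at the knife edge: a clean 2× gain has an
expected log₂ ratio of exactly 1.0, so a per-bin ≥ c rule would drop
roughly half its bins at the tumor-vs-normal cut-off no matter the
depth. With the band, a planted 2× gain of ≥ 20 bins at depth 100 per
track (4–8 tumor tracks vs one normal) is recovered with Jaccard 1.0
in practice, and a gain present equally in both groups produces no
group-contrast segment — the package's reproduction of the
chromosome-7-style artefact caveat, where a "deletion" in a group
contrast is actually an amplification shared at different intensity.

Genes are assigned to segments by ≥ 1 bp overlap in half-open
coordinates (abutting intervals do not overlap). Concordance flags a
gene when the amplified side has the higher (deleted side the lower)
mean FPKM.

## The synthetic generator

The study the pipeline re-implements deposited no raw data, so the
generator is the stand-in for it, starting at variant-call and
coverage level (no reads). One seeded RNG drives every draw; the same
(config, seed) reproduces files hash-identically.

**Variants.** Planted structures are constructed verbatim, never
sampled: group-exclusive genes, recurrent genes (one distinct variant
per group sample plus one more, so no single key is universally
shared by accident), hypermutator genes (descending distinct counts
from a configured maximum, e.g. 105), group-exclusive universally
shared keys, and cohort-universal keys. Background sharing is
controlled, not emergent — every background key is drawn in exactly
one sample — so shared structures exist only where planted. Per-group
occurrence totals and coding/deleterious counts are *exact by
construction*: the remaining occurrences are distributed
multinomially over genes already mutated in both groups (which cannot
change any set-valued structure), and annotation flags are assigned
by exact partition. The `paper-scale` preset plants the published
counts: totals 76 170 / 53 319 / 39 609 (S) and 45 903 / 33 050 /
24 328 (L), mutated-gene sets 12 714 / 11 126 with union 15 610,
hypermutated 35 / 9, recurrent 46 / 5, exclusive shared variants
17 / 2, universal 5.

Two published figures cannot be planted simultaneously with the rest
and are knowingly superseded:

* the published exclusive-gene counts 2 914 / 1 426 are arithmetically
  incompatible with the published group sets and union (12 714 − 2 914
  shared genes would force L = 11 226); the preset plants the group
  sets and union, and exclusivity follows as 4 484 / 2 896. The
  published exclusive-gene significance test is still reproduced from
  its printed counts directly.
* an M-vs-rest DEG count of 60 cannot coexist with a Venn union of
  exactly 158 under any deterministic two-sample engine (every
  reliably M-driven gene is necessarily significant in both M-pairwise
  comparisons, which would push the union to 172); the preset plants
  the Venn quantities (158 total, 112 S-L-only, 13 in common with the
  M screen) and M-vs-rest follows as 46.

**Expression.** log₂(FPKM+1) values are built from a per-gene
baseline (uniform on [3, 9]) that is constant across samples for null
genes, so with the default zero within-group noise every null gene is
exactly non-significant and recovery of the planted partition is
exact. The planted geometry: S-L-only genes shift S by Δ (default 2)
with M at the midpoint carrying a *fixed* high-spread pattern
(±4 across the three M samples — deterministic, because random draws
could land arbitrarily close together and fake a tiny Welch standard
error); three-way genes use S = +1, L = 0, M = +8; M-driven genes
shift only M by +8. A global within-group noise SD can be switched on
to exercise the stochastic path (the high-signal configuration used
in testing recovers planted S-L genes with sensitivity ≥ 0.95 at
FDR ≤ 0.1).

**Coverage.** A 3 × 30 Mb genome in 100 kb bins (900 bins), genes
placed on a uniform 5 kb grid; per-bin counts are Poisson at depth
100 with fold multipliers over the planted regions, and a flat normal
control. The preset plants a gain shared by both groups, a shared
deletion, and an S-only gain at fold 2.5 (strong enough that both the
tumor-vs-normal and the group-contrast calls clear their cut-offs
with margin).

**What the generator does not emulate.** Real mutational spectra
(all background variants are A>G SNVs at deterministic in-gene
positions), mapping artefacts, FFPE noise, overdispersed RNA-seq
counts (expression noise is Gaussian on the log scale, not
cuffdiff-like), GC/target-capture coverage bias, and subclonality
(allele fractions are not modeled). Passing the planted-recovery
tests therefore demonstrates that the pipeline's set algebra,
thresholds and statistics do what they claim — not that the
biological findings would replicate on real data.

## Problem sizes and determinism

The paper-scale run handles 122 073 variant records over a
16 610-gene universe, three pairwise DE screens plus the pooled
screen over that universe, and 900-bin coverage for 9 tracks; it
completes in a few seconds on one CPU, and the whole test suite runs
in well under a minute. All randomness flows from explicit seeds;
reruns on identical inputs produce identical outputs.

## Known limitations

* The DE stand-in is a t-test/ANOVA on transformed FPKM; it is not a
  count-model engine and makes no claim of matching cuffdiff p-values.
* The CNV caller is a thresholding contract, not a segmentation model
  (no HMM/CBS); LOH is out of scope.
* Expression tiers in the integrated report are tertiles over the
  report's own genes — a display convention, not a calibrated scale.
* The RFS-range validation (S < M < L, non-overlapping) reflects this
  study design; cohorts with interleaved survival times need their
  groups redefined upstream.
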