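# Methods

## Biological background and scope

AID deaminates cytosine to uracil, preferentially inside the WRC sequence
context (W = A/T, R = A/G); UNG normally excises the resulting uracil, so
in UNG-deficient B cells the U:G mismatch replicates into a C:G transition
fixed at the hotspot site. A tumor arising from such a cell therefore
carries (i) an excess of C:G transitions over all other substitution
classes, (ii) a concentration of those transitions in WRC/GYW context,
and (iii) — because AID keeps mutating as the tumor evolves — elevated
intratumor heterogeneity visible as a larger subclonal fraction in the
variant-allele-frequency (VAF) distribution. This package quantifies all
three signals from already-called variants; read alignment, variant
calling and consequence annotation are upstream inputs, not part of the
package.

## Panel of normals and false-positive filtering

Calls are keyed by (chrom, pos, ref, alt) after left-alignment and
parsimony-trimming of INDEL alleles, so the same event is keyed
identically across callers. "Called in a sample" means key presence in
that sample's call file regardless of the caller's PASS label, except
where a rule names the label explicitly — the set2 rule ("NO_PASS in at
most 2 samples") is meaningless under any other reading. NO_PASS counts
are taken over the tumor samples; the healthy call sets contribute
presence only. set3's "PASS in all the samples" is interpreted as PASS in
every sample *in which the variant was called* (it need only be called in
≥ `n_most` tumors); the literal reading (called and PASS in all samples)
would make set3 a subset of set2 and contradict its own ≥ `n_most`
threshold. "Called in healthy tissue" accepts either the germline or the
somatic healthy call set (configurable to one or the other).

Removal reasons are assigned with fixed precedence (panel → healthy →
known sites) so per-reason counts are reproducible when rules overlap.
Known-site matching is by full allele key by default, with a
position-only mode. The defaults `n_all = 15`, `n_most = 13`,
`max_no_pass_set2 = 2` encode the 15-tumor study design; `build_pon`
refuses a cohort whose size disagrees with `n_all` unless explicitly
overridden.

## Hotspot motif and spectrum statistics

The primary motif is the 3-mer WRC with the mutated base the terminal C;
the G-strand pattern GYW is derived mechanically by reverse complement,
and the implementation generalizes to any upstream/downstream IUPAC-set
motif. Two alternates ship: the 4-mer WRCY/RGYW, and a "printed" variant
with R = C/G. The R = C/G definition appears in some write-ups but
conflicts with the standard AID-hotspot alphabet (that set is S, not R);
the package defaults to R = A/G and keeps the variant selectable so
either convention can be reproduced exactly.

Hotspot status is a property of the reference sequence alone. A C/G whose
motif window crosses a target-interval or chromosome boundary is never a
hotspot ("edge"); edge bases still count in the total C/G denominator.
Denominators are exact single-pass counts over the capture intervals:
`n_cg`, `n_cg_hotspot`, `n_at`. Per-group frequencies are reported both as
pooled counts over the denominator (the headline, since the 2×2 tests are
built from pooled counts) and as the mean of per-sample frequencies.
Group contrasts are tests on 2×2 tables of mutated vs unmutated eligible
bases: Pearson χ² without continuity correction by default, or the exact
two-sided Fisher rule (sum of hypergeometric tables with probability ≤
observed, via `scipy.stats.fisher_exact`).

## Clonality model

Copy-neutral diploid variants sit at expected VAF = purity × CCF / 2, so
the VAF histogram is a mixture with one component per clone. The package
fits a k-component binomial mixture on (alt count, depth) by EM —
component parameters are success probabilities (mean VAFs) and mixing
weights — selecting k ∈ {1..6} by BIC (`-2·LL + (2k−1)·ln n`), from 10
k-means++-style seeded restarts per k run as one vectorized batch.
Components whose means differ by < 0.02 are merged post hoc; variants take
their maximum-posterior component. Initialization operates on the sorted
VAF vector, making results invariant to input order; the log-likelihood is
asserted non-decreasing at every EM iteration.

Screening precedes clustering with fixed precedence: depth ≥ 100 (both
filters inclusive: depth = 100 and VAF = 0.8 are kept), VAF ≤ 0.8 (to
exclude residual germline; these variants are never labeled), then CNV
overlap (copy-number-altered loci break the copy-neutral VAF model and
are excluded rather than corrected). Tumors with fewer than 10 surviving
variants are reported unclustered. The highest-mean-VAF cluster is
clonal, all others subclonal; the ITH contrast Fisher-tests the pooled
clonal/subclonal counts per group, with per-tumor proportions reported
descriptively.

Known limitation: with several hundred variants per mode, BIC occasionally
splits the clonal mode into two components ~0.04 apart — outside the merge
tolerance — inflating one tumor's subclonal proportion. The pooled group
contrast is robust to this (it moves a minority of one tumor's variants),
but per-tumor proportions should be read alongside the cluster table.

## Synthetic cohort generator

The generator emulates the cohort design the analyses assume: two
genotype groups plus one healthy control with shared germline variants.
Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| tumors | 7 WT-like + 8 KI-like | two-genotype, 15-tumor design |
| genome | 2 Mb, GC 0.42, one chromosome, whole-genome capture | desk-scale exome surrogate; GC matches mammalian exome-like composition |
| mutations/tumor | 600 (WT-like) / 800 (KI-like) | several hundred variants per tumor, KI-like higher load |
| p(C:G transition) | 0.70 / 0.80 | C:G-transition-dominated spectrum of UNG deficiency |
| hotspot weight w | 2 / 5 | moderate vs strong AID hotspot focusing |
| clones | clonal CCF 0.95 + subclones 0.30 (WT) / 0.45, 0.28, 0.15 (KI) | single minor subclone vs rich subclonal structure |
| subclonal mutation share | 0.25 / 0.50 | KI-like group carries twice the subclonal fraction |
| germline | 50 shared variants, 20% homozygous, 70% in the known-sites list | exercises every removal rule |
| recurrent artifacts | 30 loci in healthy + tumors with varying NO_PASS patterns | populates panel sets 2–3 |
| purity | 0.8 | typical bulk-tumor purity |
| mean depth | 150 (Poisson) | the ≥100-read clonality screen retains most variants; mean below ~120 would discard nearly all of a Poisson depth distribution and leave tumors unclusterable |
| INDEL fraction | 0.24 | SNV/INDEL mix of exome calling |

Mutations draw a class first (C:G transition with probability
`p_cg_transition`, otherwise uniform over the ten remaining ordered
substitution classes), then a site without replacement among eligible
bases, with hotspot C/G sites weighted w : 1. Weighted sampling uses the
Gumbel top-k construction, whose with-replacement expectation makes the
hotspot/non-hotspot rate ratio ≈ w — a closed-form oracle for the
spectrum stage (sampling without replacement depletes the hotspot pool
slightly, biasing realized ratios a few percent below w at 2000 draws).
Read support is `depth ~ Poisson(mean_depth)` (floored at 1) and
`alt ~ Binomial(depth, purity × CCF / 2)` redrawn to be ≥ 1, since a
caller only emits supported variants. A configurable fraction of records
(5%) is mislabeled NO_PASS. CNV BEDs are emitted only to exercise the
clonality exclusion filter; no VAF distortion is modeled. Genes partition
the genome into 2000 equal spans (so per-tumor gene hits are sparse
enough for group-exclusive genes to exist at this scale); consequences
draw from a fixed VEP-like vocabulary, and random subsets of genes form
the synthetic driver (120) and lymphoma (60, overlapping) sets.

All randomness flows from a single integer seed; identical configurations
produce byte-identical output trees.

### What the simulator does not model

Sequencing error and mapping artifacts beyond the labeled artifact loci;
allele-specific copy number (expected VAF is always purity × CCF / 2);
depth overdispersion or capture-efficiency variation; mutational
processes other than the single AID-like class mixture; realistic gene
structure (genes are equal-width spans, so gene hit rates are uniform).
Passing tests therefore demonstrate the correctness of the set logic, the
motif statistics and the mixture inference under the stated generative
model — not robustness to real-data artifacts such as strand bias, FFPE
damage or subclonal copy-number change.

## Numerical and design choices

- Exact tests and χ² come from scipy; the test suite cross-checks Fisher
  p-values against an independent exhaustive hypergeometric enumeration
  and χ² against the closed-form Pearson statistic.
- VCF parsing uses cyvcf2 (per-sample AD/DP first, INFO fallback; a
  missing depth field is an error, never a silent zero, because the 0.8
  VAF cutoff downstream is germline-safety-critical). FASTA access uses
  pyfaidx. The simulator writes VCF as plain text with a minimal
  conforming header.
- Positions are 1-based internally; BED conversion is confined to
  `core_io`. `NO_PASS` is any FILTER value other than the literal `PASS`,
  including `.`.
- The exclusive-gene spectrum test compares the observed C/G-vs-A/T (and
  hotspot-vs-non-hotspot) mutation split against the eligible-base split
  of the capture space; comparing one group's exclusive genes against the
  other's is also possible from the reported counts. Both are
  interpretations of an under-specified contrast and are labeled as such.
- Per-tumor clustering seeds derive deterministically from the cohort
  seed and the sample index, keeping `run-all` byte-reproducible while
  giving each tumor an independent restart stream.

## Problem sizes

Default analyses run on the 2 Mb / 15-tumor cohort (~11,000 calls). The
repeated-measurement checks in the test suite use: 100 random toy cohorts
(≤ 6 samples, ≤ 500 variants) for filter-oracle equivalence; 100 random
1 kb sequences for motif-oracle equivalence; 2000-transition single-tumor
simulations on a 100 kb genome (1 seed at w = 5, 50 seeds at w = 1) for
enrichment recovery; 25 seeded two-cluster and 10 three-cluster runs for
mixture recovery; and 50 preset-cohort replicates on a 150 kb genome for
the ITH direction-of-effect check.
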