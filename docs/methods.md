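# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. It is written for someone who wants to know *why*
the pipeline behaves as it does, not just what its functions are called.

## The scientific setting

A newly formed interspecies hybrid carries two diverged sub-genomes exposed to
one shared cellular environment. Comparing (a) orthologous genes between the
two parent species, (b) each hybrid sub-genome against its parent, (c) the two
homeologous alleles within the hybrid, and (d) every strain across two
temperatures separates three questions: how different were the parents, what
did hybridization itself change, and how does that compare with an ordinary
environmental stress. The package's contrast battery mirrors exactly this
design; its central classification asks, for every ortholog pair, whether
allelic imbalance in the hybrid was *inherited* (the parents already differed,
same direction), *acquired* (imbalance without a parental difference — the
shock component), *attenuated* (a parental difference that vanished in the
hybrid), or absent (*conserved*).

## Synthetic genome pairs

Genomes are generated by mutating one ancestral random sequence independently
along two lineages, substitutions only. With per-lineage substitution
probability q (uniform choice among the 3 alternative bases), two lineages
disagree at a site with probability d = 1 − [(1−q)² + q²/3], so
q = (3 − √(9 − 12d))/4 calibrates any requested pairwise divergence d ≤ 0.5.
The default d = 0.2 matches the coding-region divergence of the yeast species
pair this framework models. No indels means homology is positional: the same
coordinate in both genomes is homologous, gene annotations are shared, and a
simulated read's true origin pins down its correct assignment exactly. Genes
are placed without overlap (uniform random gaps via a multinomial split of the
slack), on random strands; generation fails loudly if the requested gene
density cannot fit.

Ortholog copies may differ in *annotated* length even though genomic placement
is identical: `sample_allele_lengths` draws a per-gene B/A length ratio
log-uniform in [0.8, 1.25] (1 kb base length). This emulates annotation-level
length differences between species — the thing the length-aware normalization
must absorb — without breaking positional homology.

## Count simulation

Counts are NB with var = μ + αμ². Per-gene baselines are log-uniform in
[100, 2000] (tests that need guaranteed power use [500, 2000]); dispersions α
log-uniform in [0.01, 0.3], a plausible bulk-RNA-seq range chosen as a
modeling default — the real data's dispersion distribution is not published.
Effects are split symmetrically around the baseline: a parental log2 fold
change f places the A ortholog at +f/2 and the B ortholog at −f/2, and
likewise for homeolog effects within the hybrid. Consequently a gene whose
homeolog effect equals its parental effect has a null background (hybrid vs
parent) contrast — the hybrid inherits parental expression by default, and
only genes where the two designed effects differ produce background-contrast
signal. Hybrid allele columns share one library depth factor, because they
come from one sequencing library; that is also why homeolog contrasts must not
re-normalize library size. The default scale — 300 genes, 3 replicates, 2
temperatures, 24 samples — keeps the whole battery under a second while
leaving enough genes for stable FDR behavior.

The default category mix (4% inherited, 3% acquired, 5% attenuated, 88%
conserved, effect |l2fc| = 3) reproduces the regime the framework was built to
detect: scenario fractions ≈ 0.92 / 0.05 / 0.03 for inherited-or-conserved /
attenuated / acquired.

## Read simulation and the k-mer vote assigner

Reads are uniform over the genome, both strands, with per-base substitution
errors; names encode (genome, chromosome, 0-based start, strand) so truth
never needs side files. The assigner indexes every canonical 21-mer (k odd,
11–31) of the concatenated reference with its occurrence list. A read votes
with each of its k-mers that is *exclusive* to one sub-genome; it is labelled
with the winner when the vote margin is ≥ 1, `ambiguous` on ties or margin
failures (never arbitrarily assigned, matching unique-read ASE practice), and
`unassigned` when none of its k-mers is indexed. The estimated position is the
modal read start implied by the winning genome's exclusive k-mer occurrences —
exact for error-free reads. At 20% divergence a 50 bp read has a vanishing
probability of carrying no exclusive k-mer, which is why cross-mapping is
negligible in this regime; the test suite checks the assigner exactly against
a naive oracle that re-derives every vote by substring search.

Counting is deliberately simple: a read increments the single gene whose body
(GTF closed interval) contains its start; ambiguous/unassigned reads are
dropped. This is not a transcript quantifier — it exists to measure the
*difference between counting modes*, which is what matters for cross-mapping.

## The NB Wald engine

Per gene and group, the group log-mean β solves the NB score equation
Σ (y − μ)/(1 + αμ) = 0 with μ = f·e^β, where f are normalization factors used
as multiplicative offsets. The fit is a vectorized Newton iteration (steps
clipped to ±5, 60 iterations, tolerance 1e-10) — no per-gene Python loops.
l2fc = (β₁ − β₂)/ln 2; se comes from the Fisher information Σ μ/(1 + αμ) per
group. No fold-change shrinkage is applied, because magnitude thresholds are
applied to the reported l2fc and shrunken estimates would change their
meaning. Genes with all-zero counts report l2fc 0, p 1; a group with zero
total counts is fitted against a half-count floor and flagged, not failed.

**Dispersion.** Method of moments per replicate stratum on normalized counts,
α = (s² − m)/m², pooled across strata with n−1 weights and floored at 1e-8.
A log-log mean–dispersion trend is fitted across genes, and the final estimate
is max(gene-wise, trend): with 3 replicates the moment estimator is noisy and
*underestimated* dispersions are what produce tail false positives, so only
upward deviations from the trend are trusted (symmetric log-space shrinkage
toward the trend is available via the `shrink` argument). Contrast-level runs
estimate dispersion once from *all* replicate strata of the table — 8 groups
of 3, i.e. 16 residual degrees of freedom — since dispersion is a property of
the counts, not of one contrast.

**Reference distribution.** With dispersions supplied as known, p-values are
two-sided normal on l2fc/se. When the engine estimated the dispersions itself
it uses a t reference with the estimation's residual degrees of freedom — the
classical small-sample correction for plugging in an estimated variance. The
combination (upward-only dispersion pooling + t reference) is what makes the
conserved-only null design produce empty DE sets at the strict thresholds
while keeping ≥90% power at |l2fc| = 3, μ ≥ 500: tested properties, not
aspirations.

**Normalization.** `size_factors` is the median-of-ratios estimator rescaled
to geometric mean 1. `allele_length_factors` divides each gene's lengths by
their per-sample geometric mean (per-gene factors multiply to 1 — no hidden
library-size component). `length_and_library_factors` multiplies length
factors by size factors computed on length-corrected counts, for
cross-species contrasts where both depth and annotated length differ.

**Multiple testing** is Benjamini–Hochberg (statsmodels' step-up behind the
`adjust_bh` surface, with NaN pass-through); DE calls use strict inequalities
|l2fc| > 1.5 and padj < 0.01, with an optional base-mean ≥ 10 filter for the
relaxed-threshold analyses. The relaxed cross-mapping concordance filter is
|l2fc| > 1, padj < 0.05.

## Contrast conventions

parents = log2(A/B) at one temperature with length-and-library normalization;
backgrounds = log2(hybrid/parent) per species, library-size normalization
(same genome, lengths cancel); homeologs = log2(allele A / allele B) within
the hybrid, allele-length-only normalization; temperature = log2(cold/warm).
The DE universe for inheritance classification is the one-to-one ortholog
set; pairs DE in both contrasts with *opposite* signs are classified
`acquired_ASE` and flagged `reversed`, because the same-direction rule
excludes them from inheritance. Temperature-dependent ASE is an interaction
Wald test — the difference of the per-temperature homeolog l2fcs with pooled
se, t reference with the dispersion df — rather than a set difference of
per-temperature ASE lists, which would conflate threshold noise with real
condition dependence.

## ATAC analysis

All BED-family coordinates are 0-based half-open; GTF is 1-based inclusive and
converted at the boundary; overlap means ≥ 1 shared base (configurable
nowhere lower). Replicate consensus clusters overlapping peaks across
replicates and keeps clusters supported by ≥ 2 of 3 replicates (the union
interval, mean score). The parent/hybrid partition is reported from each side,
so parent-consensus + parent-specific always equals the parent set size. Score
comparison is a two-sided Wilcoxon rank-sum (exact for small tie-free groups,
normal approximation with tie/continuity corrections otherwise); the "score"
is the narrowPeak score column.

Promoters extend from a gene's 5′ end upstream until 1 kb, the nearest
annotated gene body, or the chromosome edge, whichever is closest, with the
truncation reason recorded; zero-length promoters (abutting genes) are emitted
but excluded from counting. Promoter "counts" are summed per-base bedGraph
coverage — a proxy for fragment counts chosen because real fragment counting
needs BAMs, which are out of scope; real-data users can supply read counts
directly. Differential accessibility reuses the NB engine with
allele-length-style factors built from promoter lengths and calls at
|l2fc| > 1, padj < 0.01. Peak→gene links require the gene body within 1 kb of
the peak *and* ≥ 1 bp promoter overlap, nearest gene per strand; integration
joins links (or DA calls) against DE results and reports same-direction /
opposite / no-DE concordance counts.

The ATAC simulator places peaks on promoter-like template intervals with a
designed shared fraction between backgrounds, lower mean scores for
background-specific peaks, bounded per-replicate coordinate/score jitter, and
box-sum coverage tracks. Its shared fraction is recovered by the partition to
within ±2% at 3000 peaks.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the study — effect classes,
shared-library allele pairs, length asymmetries, replicate jitter, designed
peak sharing — with clean NB noise, uniform read positions, no indels, no
transcript structure (introns/UTRs/isoforms), no sequencing-quality model, no
GC or transposase bias, and independent genes. Passing tests therefore
demonstrate that the *estimators and classifiers are correct under their
stated model*, including length-bias removal and calibration under the null;
they do not demonstrate robustness to real-data pathologies (mappability
artifacts, correlated genes, outlier replicates). Real-data mode consumes
externally produced count tables and peak sets precisely because alignment
and peak calling are better done by dedicated tools.

## Problem sizes and reproducibility

Default scales — 2 × 100 kb genomes, 300 genes, 3 replicates, 10–20 seed
replications in recovery checks, 3000 peaks for partition recovery — were
chosen so each module demonstrates its statistical claims at seconds-scale
cost. Every generator is a pure function of (parameters, seed); the pipeline
derives per-stage seeds from one master seed by fixed offsets, stamps every
artifact with the config hash and stage seed, and reruns byte-identically.

## Known limitations

* Two-group contrasts plus one interaction only; no general design matrices,
  no outlier replacement, no independent filtering by default.
* Dispersion estimation is moment-based with trend flooring — simpler and
  more conservative in the tails than full empirical-Bayes machinery; at
  large replicate numbers it is mildly conservative.
* The per-sample normalization-equivariance of the estimator is exact only in
  the Poisson limit (the NB score weights samples by their factors); global
  rescalings are exact at any dispersion.
* The k-mer assigner ignores base qualities and does not model spliced or
  clipped alignments; it is a measurement device for cross-mapping contracts,
  not an aligner.
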