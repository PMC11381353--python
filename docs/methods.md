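# Methods

## Scope and data model

The pipeline starts from *read assignments* and *count matrices* — i.e.
after adapter trimming, alignment and per-gene assignment have been done by
external tools — and covers classification, quantification, normalization,
differential expression, set logic and enrichment. Intervals are stored
0-based half-open; GFF3 is converted on input, BED taken natively. A read
assignment carries (gene, length, 5′ base, orientation relative to the
gene, weight); identical records may be collapsed with summed weights, and
every downstream tally is weight-additive, so collapsed and per-read
representations are interchangeable (this is exercised by a round-trip
test). A SAM record overlapping *k* genes contributes weight 1/*k* to each
by default (`--primary-only` instead assigns it to the longest overlap,
ties broken lexicographically); read length is the number of bases in the
record's sequence, since the siRNA class is a property of the molecule,
not of its reference span.

## Small-RNA taxonomy

A read is a 22G-RNA iff it is 22 nt with a 5′ G and antisense to its
assigned gene; a 26G-RNA iff 26 nt, 5′ G, antisense. Two switches modify
the rule: `include_21nt_trimmed` admits 21-nt 5′G reads into the 22G class
(adapter trimming can clip one base — useful for locus-level profiles, off
by default so that class bar-graph counts mean literal 22-mers), and
`require_antisense=False` drops the orientation requirement (the default
for class counting keeps it, since siRNAs are antisense by biogenesis; the
mir-35-family counter bypasses classification entirely and counts every
read mapping to a family member, because mature miRNAs are sense-strand
products). Profile matrices tally weighted reads over length (default
window 18–30 nt, matching the library size selection) × first base;
out-of-window lengths go to a QC counter, not the matrix.

The small-RNA RPM denominator is the library's total weighted reads inside
the length window assigned to any annotated feature, configurable to a
caller-supplied total (e.g. all genome-mapped reads): the published
denominator is not stated, so both policies are surfaced.

## Normalization and replicate-level tests

RPM = counts × 10⁶ / library total. Cross-stage summaries divide a class's
summed RPM by a normalizer measured in the same library: the summed RPM of
the mir-35 family (*mir-35*–*mir-42*; germline-expressed, *mutator*-
independent, so it tracks gonad-derived RNA content across stages) for
small-RNA classes, or *rpl-32* RPM for mRNA. The ratio is invariant to
uniform depth rescaling, and identical whether raw counts or RPMs are
divided. Summaries keep one value per biological replicate; the two-sample
tests operate on those replicate values (n = 2–3), never on pooled counts.
Welch and Student *t* use the standard scipy fits; the Wilcoxon rank-sum
uses full rank-assignment enumeration (midranks for ties) when
n₁+n₂ ≤ 10 — at most C(10,5) = 252 assignments — and otherwise a normal
approximation with tie and continuity corrections. One-tailed directions
must be given explicitly in config; none is inferred. Degenerate
zero-variance inputs return p = 1 (equal means) or a flagged p = 0.

## Differential expression

Pairwise contrasts under a negative-binomial model:

1. **Size factors** — median-of-ratios over genes nonzero in all samples.
2. **Dispersion** — per-gene method-of-moments α̂ = (v − m)/m² using
   within-group variances pooled over both groups (so true mean differences
   do not inflate α̂), a trend α(m) = a₁/m + a₀ fitted by iteratively
   trimmed least squares (16-fold outliers dropped), and log-scale
   shrinkage of the gene estimate toward the trend with weights
   (residual df) : (prior df = 6). A gene whose moment estimate is
   non-positive carries no dispersion information and takes the trend
   value. With n = 2 per group (the L4 design) shrinkage is maximal and a
   warning notes the limited power.
3. **Wald test** — log₂FC from the fitted group means of normalized counts
   (a zero group mean takes a half-read-per-library floor so the estimate
   stays finite); SE from the NB log-link information,
   SE² = (1/Σw_A + 1/Σw_B)/ln²2 with w = μ/(1+αμ); two-sided normal p.
4. **BH adjustment** over genes with positive base mean; all-zero genes are
   excluded and reported.

Calls use strict |log₂FC| > 1 (down: < −1) and inclusive p_adj ≤ 0.05.
No independent filtering and no post-hoc fold-change shrinkage are applied;
this is the simplest defensible equivalent of the standard NB Wald
workflow, and the null calibration and planted-recovery checks in the
acceptance suite quantify what it delivers (raw p < 0.05 fraction ≈ 0.05
on null data; sensitivity ≈ 0.9 at 4-fold effects, observed FDR ≈ 0.01–0.03
at n = 3).

**Exclusive sets.** The three contrasts are heat-only (WT 25° vs WT 20°),
mutation-only (mut-16 20° vs WT 20°) and combined (mut-16 25° vs mut-16
20°; two alternative definitions of "combined" are selectable in config
since the published description is ambiguous). A gene called in either
direction in a single-factor contrast is removed from both exclusive sets
(direction-blind exclusion — "any differential expression" reads
direction-blind).

## Enrichment

Fisher's exact test, two-tailed by the point-probability rule (sum of all
tables at most as probable as observed), on (k, n−k, K−k, N−n−K+k). The
universe defaults to the genes tested in the corresponding DE comparison
(base mean > 0) — the conservative choice, since the published universe is
unstated — configurable to all annotated genes. Effect size is
log₂((k/n)/(K/N)); an empty overlap renders the sentinel `-INF` in text
output and null-plus-flag in JSON. Class-level log₂FC distributions are
compared with the two-sided Wilcoxon above; multiple-comparison adjustment
for families of such tests defaults to BH (Holm and Bonferroni available).

## Synthetic data generator

The generator defines the study conditions everything is validated under:

* **Design** — 2 genotypes × 2 temperatures × 2 stages; 2 biological
  replicates per L4 condition and 3 per adult condition, for both assays.
* **Classes** — scaled-down curated lists (default 400 sperm, 250
  oogenesis, 200 sex-neutral, 60/60/100 ALG-3/4 negative/positive/other
  nested inside the sperm class, 360 CSR-1, 30 ERGO-1 targets, in a
  2000-gene universe) built deterministically with requested pairwise
  overlaps; infeasible requests fail before sampling, and realized sizes
  are exact by construction.
* **mRNA** — NB counts (dispersion 0.05) around log-normal baselines
  (log-mean log 100, log-sd 1.5, expected depth 10⁶). Curated-class
  members draw their baselines from the same distribution left-truncated
  at an expected 50 reads: the emulated lists are *defined* by expression
  enrichment, so silent members would be unfaithful to what they
  represent. Planted log₂FC by class, genotype, temperature and stage;
  the default matrix is the sperm switch (−1.5 in mutant L4 at 25 °C,
  +2.0 in mutant adult at 25 °C, oogenesis flat), with *alg-3*/*alg-4* as
  named genes following the sperm pattern. A developmental baseline
  multiplier (sperm high at L4, oogenesis high in adults) shapes
  cross-stage profiles without entering the within-stage contrasts.
* **Small RNA** — per gene, Poisson read totals for a 22G pool, a 26G pool
  and a background pool, each expanded multinomially over (length, 5′
  base, orientation): peak length probability 0.9, 5′G probability 0.85,
  antisense probability 0.95 for siRNA pools; uniform background. Because
  the two stages are independent, class proportions are analytically known
  and the thinning ratios below are recoverable by Monte Carlo. 22G pools
  of *mutator*-dependent classes are thinned ×0.25 in the mutant (×0.5
  further at 25 °C); CSR-1-class 22Gs are instead thinned ×0.5 by heat in
  both genotypes; 26G pools are thinned ×0.2 only under mutant × heat.
  The mir-35 family is 8 members at 2000 expected reads each, sense-strand,
  condition-independent; *rpl-32* is a stable high-abundance mRNA.
  The per-class 22G/26G abundance ratios are order-of-magnitude choices
  (not printed in any source) and are exposed in the config.

What passing tests do **not** show about real data: the generator has no
multimapping ambiguity, no positional or sequence-composition biases, no
correlation between genes, no batch effects, and dispersion constant
across genes — so recovery rates here are an upper bound on what the same
thresholds would achieve on real libraries.

## Problem sizes and tolerances

Unit tests run a scaled configuration (500-gene universe, depth 2.5×10⁵)
sharing the default structure; the acceptance checks use the full default
(2000 genes, depth 10⁶) for the end-to-end run, 2000/5000 genes for DE
calibration/recovery, 200 random tables for the Fisher oracle (agreement
to 10⁻¹²), all group sizes n₁+n₂ ≤ 10 for the Wilcoxon oracle, and 20
seeds for the depletion estimate. Numerical conventions: conservation and
invariance properties hold to 10⁻⁹ relative; dispersion floor 10⁻⁸; BH
ties broken stably; lexicographic tie-break for primary-only SAM
assignment; boundary p_adj = α is called, boundary |log₂FC| = 1 is not.

## Known limitations

* Pairwise contrasts only — no interaction GLM; the exclusivity logic is
  the set-theoretic counterpart used in the emulated analysis.
* No independent filtering, fold-change shrinkage or outlier replacement
  in DE; results are not intended to be bit-identical to any specific DE
  package.
* The Wilcoxon normal approximation is used above n₁+n₂ = 10; exact
  enumeration is not attempted for large samples.
* TPM and genome-browser/PCA outputs of external quantifiers are out of
  scope; RPM is the implemented unit.
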