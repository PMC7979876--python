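# Methods

This note documents the models and procedures somaseq implements, the
parameters that matter, the numerical choices made where a published
description leaves the construction open, and what the synthetic-data
generators do and do not emulate.

## Somatic SNV calling by subtraction

The pipeline assumes tumour and matched-normal call sets produced
independently by the same caller, carrying FreeBayes-style annotations:
AO/RO (alt/ref observation counts), SAF/SAR and SRF/SRR (per-strand
splits of each), QA/QR (summed phred base qualities), MQM (mean mapping
quality of alt observations), SAP (phred-scaled strand-balance
probability), AB (ref-read fraction, carried but never filtered on), and
NUMALT (ALT alleles at the site).  Multi-allelic sites are expanded to
one record per ALT allele with NUMALT preserved, so the site-level
`NUMALT < 2` condition keeps its meaning after expansion.

Stages, in order: (1) initial filter `QUAL > 1 & NUMALT < 2 & SAF > 1 &
SAR > 1` applied to both samples; (2) subtraction of germline calls
matching on `(CHROM, POS, ALT)` — REF is deliberately not part of the
key, as the ALT allele at a position identifies the variant; (3) removal
of strand-biased calls; (4) final filter `AO > 10 & RO > 10 & QA > 100 &
QR > 100 & AO < 100 & RO < 100 & SAP < 30 & MQM > 55`; (5) optionally,
subtraction of a second germline call set from another platform.  All
comparisons are strict inequalities.  Indels and MNPs are dropped up
front with a logged count: the thresholds are calibrated for
single-nucleotide substitutions.

**Strand-bias operand.** The 4× rule compares *per-strand alt
fractions* — SAF/(SAF+SRF) against SAR/(SAR+SRR) — rather than raw SAF
vs SAR.  Raw counts would penalise uneven strand *coverage* twice; the
per-strand fraction isolates allele imbalance from coverage imbalance.
A strand with zero total depth contributes fraction 0, so such a call is
removable only when the other strand's fraction is positive.  The
comparison is strictly greater: a ratio of exactly 4 is retained.

Each filter is a pure per-record predicate, so the stage functions are
idempotent and commute; the pipeline can never introduce a call.

## Somatic SV derivation and benchmarking

Germline subtraction removes a tumour SV when a germline SV of the same
type has both breakpoints within L/100 bases, L the germline SV length.
Two deliberate extensions where that rule is inapplicable:

* translocations have no length, so they subtract within a fixed window
  (default 1000 bp, the cross-method matching tolerance);
* the tolerance has a 10 bp floor, because L/100 falls below typical
  breakpoint jitter for SVs under 1 kb and a re-called germline twin
  should still subtract.

The somatic filter keeps precise calls longer than 10 kb (strict) with
neither breakpoint on the decoy contig hs37d5; imprecise calls with
AF > 0.2 are routed to a side collection for separate review rather than
silently dropped.  Translocations are exempt from the length condition —
their length is undefined, and applying it literally would remove every
translocation.

**Cross-method matching** treats two calls as the same variant when the
type matches and both breakpoints agree within a tolerance (default
1000 bp).  Unique variants are the connected components (transitive
closure) of this pairwise predicate, computed by union–find, rather than
a greedy sweep in sorted order: connected components are invariant under
permutation of the input call sets and have an obvious exhaustive
oracle, whereas greedy assignment on chains is order-dependent.  With a
1 kb tolerance and SVs over 10 kb, chains that would merge distinct
variants require pathological breakpoint spacing.

**Evaluation** takes truth labels as an input (they come from manual
review or, in tests, from the simulation truth); the harness makes no
attempt at automated truth assessment.  Per SV type and method,
FNR = (true variants the method missed)/(total true variants) and
FDR = (false calls the method made)/(all calls the method made) — the
FDR denominator is the method's call count, not the true-variant count.
A zero denominator yields NaN, never 0.  Tabulated rates are rounded to
two decimals, half-up.  Because the true-variant universe is the union
of what the methods found (plus labels), FNR estimates are lower bounds
when a variant escapes every method; with three methods at ≤15% miss
rates this bias is below 0.005 and well inside the binomial error the
tests allow.

## Windowed copy number, purity and ploidy

Inputs are read counts per 100 kb window (MAPQ ≥ 20 counting is assumed
upstream; the package consumes the table).  The normalised log ratio is

    R(w) = log2(T(w)/N(w)) − offset,   if N(w) > mean(N) − 2·sd(N)
           missing,                     otherwise

with sd the sample standard deviation.  The offset defaults to
log2(total tumour count / total normal count), generalising a fixed
yield ratio; any residual error in it is absorbed by the recentring
step.  Windows with T(w) = 0 are masked with a logged count rather than
carrying −∞.  The mask is strictly greater-than; in the degenerate case
sd(N) = 0 every window sits exactly at the threshold and is masked,
which only arises for constant synthetic input.

**Circular binary segmentation.**  Each chromosome's unmasked sequence
is segmented recursively.  The split statistic is the Olshen-style
circular two-segment statistic: over every arc x[i:j] whose length and
complement are both at least `min_width`, the maximum of
|mean(arc) − mean(rest)| / sqrt(1/k + 1/(n−k)).  An arc and its
complement describe the same circular partition, so ties are
canonicalised to the smallest (i, j).  Significance is assessed by
permutation: the p-value estimate (exceedances+1)/(trials+1) against
`alpha`, with early stopping once the exceedance count forces
p ≥ alpha, or once 2/alpha clean trials bound p below it; comparisons
use a 1e-9 tolerance so the decision is stable under floating-point
reordering.  Accepted splits cut at i and j and recursion continues on
the pieces.  Finally sd-undo merging removes change points whose
adjacent segment means differ by less than `undo_sd` point-level SDs,
weakest first; the point-level SD is estimated robustly as
1.4826·median(|successive differences|)/√2, which is insensitive to the
segment jumps themselves.  Defaults: alpha = 0.01, min_width = 5,
undo_sd = 3, n_permutations = 1000, seeded.  On sequences of length
≤ 12 the implementation is verified against an exhaustive search over
all change-point placements using the same statistic and tie-break.

**Recentring.**  The diploid baseline is the window-weighted mean of
segments with more than 500 windows whose mean lies within a zero band
(default 0.25) of zero; it is subtracted from all segment means.
Weighting by window count matches "the mean of the points in the
segments".  If no segment qualifies the pipeline stops with an error
asking for a manual baseline rather than guessing.

**Purity.**  For tumour copy number p at purity α over germline ploidy
g, the expected segment mean is m = log2((αp + g(1−α))/g): zero at
p = g, −∞ at α = 1, p = 0, strictly increasing in p for α > 0.
Aberrant autosomal segments (|mean| ≥ zero band) are clustered in one
dimension by splitting sorted means at gaps larger than `cluster_gap`
(default 0.15); the most negative cluster is taken as single-copy loss
(p = 1) and the positive clusters, ascending, as gains to p = 3 and
p = 4 — a warning is emitted if the cluster count differs from that
expectation.  Each cluster mean inverts to α = (2^(m+1) − 2)/(p − 2)
and the estimates are averaged.  The zero band that separates diploid
from three-copy segments only does so for α above roughly 0.35; for
noiseless synthetic input with no neutral segments the band can be set
to 0, under which the inversion round-trips to machine precision for
α ∈ [0.2, 0.95].

**Classification** assigns each recentred segment the copy number in
0–6 whose theoretical mean (using germline ploidy 2 for autosomes, 1
for X/Y of an XY genome) is nearest; ties break toward the lower copy
number, and an optional distance cap leaves outliers unclassified.

## Cis/trans expected-VAF model

For a somatic SNV co-located with a heterozygous deletion carried by x%
of all cells in a sample of purity π% (0 ≤ x ≤ π), allele copies number
2 per 100 cells without the deletion and 1 per deleted cell, giving
200 − x copies per 100 cells.  In *cis* the SNV survives only in tumour
cells that escaped the deletion: VAF ≤ 100(π − x)/(200 − x), decreasing
in x, maximal at π/2 when x = 0.  In *trans* every tumour cell carries
it: VAF ≤ 100π/(200 − x), increasing from π/2 to 100π/(200 − π).  Both
are upper bounds because the SNV may itself be subclonal.  The decision
rule follows: an observed VAF strictly above π/2 is impossible in cis
and supports trans; one below both the cis curve at the deletion-implied
x and the trans minimum supports cis; the boundary is inconclusive.  A
helper inverts the deletion's own allele fraction to a cell fraction
(x = 200·AF/(1 + AF)); since caller-reported AFs mix allele and cell
fractions, its output is treated as indicative only.

**Haplotagging** is a deliberate simplification of read-backed phasing:
given two phased haplotypes over heterozygous sites, each read votes at
every covered site for the haplotype whose allele it shows; strict
majority assigns the read, ties and uninformative reads stay
unassigned; no recombination or error model is used.  For reads
covering k sites with per-site error e, assignment is wrong when a
majority of sites flip — probability P(Bin(k, e) > k/2), about 0.0086
at k = 5, e = 0.1 — which the tests check against observed accuracy.

## Synthetic data

The generators produce inputs with the statistical structure the
pipelines assume, at the scale of a single-patient tumour/normal
experiment: per-sample depth around 60×, tumour purity 0.6–0.63, a
chromosome-scale copy-number landscape with whole-chromosome changes to
4, 3, 3 and 0 plus a single-copy loss, clonal somatic SNVs, and SV
inventories in the tens with a handful of false calls per method.

* Small variants: germline heterozygotes at VAF 0.5 in both samples,
  somatic SNVs only in the tumour at VAF = purity·cell-fraction/2,
  counts binomial at a Poisson (or negative-binomial) depth, QA/QR
  proportional to counts at mean base quality 30, MQM normal around 60,
  SAP the phred-scaled two-tailed binomial probability of the strand
  split.  The external caller's SAP definition differs in detail, but
  the pipeline only thresholds SAP, so any calibrated monotone
  strand-imbalance score serves.  Planted strand artefacts put all but
  two alt reads on the forward strand and all ref reads on the reverse,
  which guarantees removal by the 4× rule while still clearing the
  initial filter's SAR floor.
* SVs: germline events appear in both samples with breakpoint jitter at
  most L/200 (inside the subtraction tolerance by construction);
  per-method call sets drop each true somatic SV with a configured
  per-type miss probability and add decoy-contig calls, imprecise
  low-AF noise, and germline leak-throughs shifted just past L/100.
* Window counts: negative-binomial with variance μ + φμ² (φ = 0 gives
  Poisson; default φ = 1/300, mild overdispersion), normal-sample mean
  60 per window, tumour mean scaled by (αp + g(1−α))/g; about 1% of
  windows get near-zero normal counts to exercise the mask.
* Phased reads: contiguous runs of 5 sites from one of two haplotypes
  with a per-site allele-flip error.

Identical seeds give identical outputs; every generated file parses
back through the package's own readers.

What the generators do **not** emulate: reference-sequence context and
alignment artefacts (mapping bias, segmental duplications, GC waves),
correlated noise along the genome, caller-specific quirks in annotation
values, subclonal copy-number mixtures, and read-level sequences.
Passing tests therefore demonstrate that the algorithms implement their
definitions and recover planted truth under the stated noise models —
not that the thresholds are optimal for any particular instrument.

## Problem sizes and known limitations

The default copy-number simulation uses 2550 windows across six
chromosomes — large enough that segment means estimate to ±0.015 and
purity to about ±0.025, comfortably inside the ±0.03 the tests assert —
and the stochastic suites use hundreds of SVs or reads so binomial
tolerances stay tight.  The log-ratio of count ratios carries a small
Jensen bias that differs between copy-number states, which shows up as
a purity overestimate of roughly +0.01 at depth 60; it shrinks with
depth and is documented rather than corrected.  The CBS permutation
test is approximate (early stopping, seeded); sd-undo uses a robust
point-SD estimator rather than the segment-residual estimator some
implementations use, which can merge genuinely weak change points.
Purity estimation assumes the aberrant clusters correspond to copy
numbers 1, 3 and 4; genomes whose gains sit elsewhere need the cluster
assignment reviewed (the warning flags unexpected cluster counts).
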