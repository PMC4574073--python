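# Methods

## Overview

`repstab` analyses tandem-repeat instability in paired tumor/normal
genomes.  Its pipeline has four scientific stages:

1. **Tandem repeat detection** in per-gene promoter and exon
   "super-transcript" regions;
2. **Instability calling** per genome pair: repeats are matched across the
   two genomes of a pair and classified as *stable*, *unstable* (repeat-unit
   copy number changed) or *orphan* (present in only one genome — a de-novo
   gain or a loss);
3. **Cohort statistics**: per-pair gene counts compared between
   tumor–matched-normal pairs (one per patient) and the all-pairs
   normal–normal null (all C(n,2) unordered pairs of normal genomes,
   pooled), with MSI-vs-MSS and per-pathway variants;
4. **Omics association**: per gene, mean expression (rpkm) and promoter
   methylation (beta) compared between tumors where the gene shows promoter
   instability and tumors where it does not, tested across genes with the
   Wilcoxon signed-rank test.

A synthetic-data generator produces complete cohorts with ground truth so
every stage is testable without access to controlled human data.

## Repeat detection

A tandem repeat is an array of a repeated unit of 1–100 bp.  An array is
reported when, aligned globally against cyclic concatenations of its
consensus unit (wraparound dynamic programming; the array is fully
consumed, the start/end phase in the unit is free):

* alignment score ≥ 80, with weights +2 per match and −7 per mismatch or
  indel (the Tandem Repeat Finder defaults; a perfect array therefore
  needs ≥ 40 bp);
* unit identity ≥ 0.90 (matches / aligned unit positions);
* indel fraction ≤ 0.10 (indels per adjacent-unit junction spanned);
* at least two full copies (`min_copy_number = 2`); without this floor,
  any 40-bp window would count as one "copy" of itself at period 40.

The consensus unit is the most frequent full-length chunk of the array at
the candidate period (ties broken lexicographically); units are reported
in canonical form (lexicographically minimal cyclic rotation).  Units that
are whole-number powers of a shorter unit are not reported separately —
the primitive-period description of the same locus always takes
precedence.  `N` bases match nothing; candidates with more than 10 % `N`
are discarded.  Coordinates are 0-based, half-open, region-relative.

Overlap resolution: candidates are ranked by score, then length, then
leftmost start, then smallest period; a candidate is suppressed by an
already-accepted one when they share a canonical unit and overlap at all,
or have different units and overlap by ≥ 50 % of the shorter.

### Search strategy and exactness

The search is seeded — candidate periods are proposed from runs of
sequence self-matches at distance *p* — and candidate (start, length)
spans are pruned with *provable necessary conditions* derived from the
thresholds (bounds on the number of distance-*p* self-mismatches a passing
array can contain, in total and per disjoint block, and on candidates
whose consensus is provably non-primitive).  Surviving candidates are
verified by the wraparound alignment, lazily: a candidate is only aligned
when an admissible score upper bound says it could still beat every
accepted candidate.  The pruning conditions never exclude a passing
candidate, so the output equals that of the exhaustive search; the package
ships the exhaustive reference (`repstab.bruteforce`) and the acceptance
suite verifies exact agreement on 1,000 random sequences.

Inner loops (alignment, consensus, candidate enumeration) use
numba-compiled kernels when numba is importable, with semantically
identical pure-Python fallbacks.

## Matching and instability calling

Repeats in the same gene region of two genomes are matched when they share
a canonical unit and their starts differ by ≤ 50 nt (tolerating
indel-driven positional shifts).  Matching is one-to-one and greedy by
increasing positional distance (ties: higher summed score, then smaller
start); greedy matching is deterministic and agrees with optimal
assignment on the small per-region repeat counts seen in practice.  A
matched pair with |Δ copy number| ≥ 1 full unit is *unstable*
(`unstable_min_delta`, exposed; the one-unit floor guards against
fractional copy-number jitter from boundary trimming — a 10⁻⁹ tolerance
absorbs float error in length/period ratios).  Unmatched repeats are
orphans: an orphan on the tumor side is a gain, on the normal side a loss.
Reverse-complement units are *not* identified by default (strandedness of
the annotation is respected; `identify_revcomp` switches this).  Matching
never crosses gene boundaries.

A gene is *repeat-instable* in a pair if any of its matches is unstable or
orphan; it is counted once regardless of how many repeats qualify.
Mononucleotide flags restrict to repeats whose canonical unit is a single
base.  The gene × patient matrix collects tumor-vs-matched-normal
instability flags; genes with no instability in any patient are dropped
before association analyses (they carry no contrast).

## Cohort statistics

Per-pair profiles count genes with orphan / unstable / either type of
instability, per region kind, with mononucleotide counterparts, and
per-pathway *proportions* (denominator: all pathway genes in the analysed
set, not only repeat-bearing ones — exposed as a design option).  Group
comparisons use the two-sided Wilcoxon rank-sum test: exact permutation
null when the smaller group has ≤ 8 observations and the pooled values are
tie-free, otherwise the normal approximation with tie and continuity
correction.  Two identical constant groups give p = 1.  Bonferroni
correction multiplies p by the family size and caps at 1; families follow
the figure-level groupings (four MSI panels; pathways × event types).

## Omics association

For each gene in the instability matrix, the mean of its expression over
instability-flagged tumors and over the remaining tumors is computed;
genes flagged in all or no tumors are excluded.  The per-gene pairs
(log2(mean + ε), with ε = 10⁻⁶, mean-then-log order) are compared with the
two-sided Wilcoxon signed-rank test (zero differences dropped; exact null
for ≤ 25 tie-free nonzero pairs, else normal approximation).  The reported
direction is the sign of the median paired difference.  Methylation uses
the identical scheme on beta values without the log transform.  Expression
is compared across tumors only; no tumor-vs-normal expression contrast is
computed.

## Synthetic cohorts

The generator emulates the study design: `n_genes` genes, each with a
promoter (default 5,000 bp) and an exon region (default 500–2,000 bp);
a configurable fraction of regions carries one perfect planted repeat
(unit length from a microsatellite-like spectrum over 1–6 bp, 30 %
mononucleotide; copies drawn from 3–15 and raised so the array stays
detectable with one unit of headroom).  Backgrounds are i.i.d. uniform
A/C/G/T, rejection-sampled so the only detectable repeat in a region is
the planted one — this keeps the truth table exhaustive.

Each patient's germline genome receives private slippage at half the
normal–normal rate (so two normals differ at ≈ `p_slippage_normal`); the
tumor genome adds somatic events per locus, mutually exclusive per
region: copy-number change at `p_slippage_tumor` (× `msi_rate_multiplier`
for MSI patients, capped at 1), loss of the planted array (replaced by
validated background), or a de-novo gain (validated array with a unit
distinct from the planted one).  Copy changes add or remove k whole
units, k geometric (p = 0.5), sign flipped to + when a loss would make the
array undetectable.  Expression is 2^N(5, 0.8) rpkm with an additive
`expr_effect_log2` (−1 by default) on (gene, tumor) combinations whose
promoter is instability-flagged; methylation is N(0.30, 0.05) + 0.10 on
the same combinations, clipped to [0, 1].  `meth_noise_sd` is a generator
parameter (a noise scale is required to draw beta values at all).

Default rates (`p_slippage_normal` 0.016, `p_slippage_tumor` 0.08,
multiplier 10, gains/losses 0.05) are free parameters chosen once for
statistical power at n = 35 patients; they are not estimates of human
biology.  Event draws are separated from sequence rendering: the
event-level fast path powers replicate studies, and rendering is
separately proven lossless (precision = recall = 1 against the truth), so
composing the two is sound.

What the generator does **not** emulate: realistic genome composition and
GC structure, imperfect planted repeats (the detector's tolerance to
imperfection is exercised by its own tests instead), sequencing noise,
germline gains/losses, SNV/indel background outside repeats, and
correlated gene expression.  Passing tests therefore demonstrate
correctness of the machinery under the stated generative model, not
performance on real tumor genomes.

## Problem sizes used in validation

Truth recovery runs a rendered cohort of 200 genes × 35 patients with
420-bp promoters and 260–420-bp exons; power, calibration and
effect-recovery studies use 200 event-level replicates at 200 genes × 35
patients (4 MSI / 31 MSS, mirroring the cohort split); the
detector-vs-exhaustive-search comparison uses 1,000 random sequences of
60–500 bp, two-thirds carrying a planted, lightly mutated repeat.  The
synthetic-cohort pipelines cap the detection unit length at 20 bp
(planted units are ≤ 6 bp); the detector itself supports the full 1–100 bp
range.

## Known limitations

* **The all-pairs normal–normal null is anti-conservative.**  The C(n,2)
  pooled pairs share genomes, so their per-pair counts are correlated
  (≈ 0.5 between pairs sharing a genome), violating the rank-sum test's
  independence assumption.  Under equal generative rates the
  tumor-vs-normal comparison rejects at ≈ 24 % instead of 5 % at this
  cohort size; with independent (disjoint) normal pairs the same test is
  calibrated.  Reported p-values for the all-pairs contrast should be read
  as descriptive of that design.
* **The mean-then-log expression scheme is biased at small group sizes.**
  log2 of the mean of k lognormal values has expectation depending on k
  (≈ −CV²/(2k ln 2)); instability groups are systematically smaller than
  their complements, so paired log-mean differences are negative even with
  no effect (≈ 40 % rejection under the null at 200 genes with ~6-tumor
  groups).  The effect direction and magnitude reported at genome scale
  should be interpreted net of this bias; the linear-scale methylation
  analysis is unbiased.  Both phenomena are flagged by the calibration
  studies rather than hidden by them.
* Greedy matching is compared to optimal assignment only on small cases;
  regions with many same-unit repeats could in principle differ.
* The generator plants at most one repeat per region plus at most one
  gain, so multi-repeat regions are exercised only lightly end-to-end.
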