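# Methods

## Study design being modeled

Ten individual trees are sampled across a wood-volume gradient and sequenced
once each (no biological replicates): rRNA-depleted libraries quantified as
FPKM for mRNAs and lncRNAs, small-RNA and back-splice libraries quantified as
TPM for miRNAs and circRNAs.  Wood volume is a deterministic function of
height (m) and diameter at breast height (cm),

    VW [m^3] = 6.01228e-5 · DBH^1.8755 · HT^0.98496,

a species-specific allometric equation; `assoc.volume_of_wood` evaluates it
exactly and is strictly increasing in each argument on the positive orthant.

The two extreme individuals (highest and lowest VW; by convention SS1 and the
last sample) anchor all comparative analyses.

## Differential expression without replicates

With one library per tree, the dispersion of a negative-binomial count model
is not estimable from the data; it is an explicit, fixed parameter of the
test (`DeParams.dispersion`, default 0.1; the pipeline uses the simulation's
generative dispersion).  For a pair of samples, the test conditions on the
pair total N: under the null of a shared underlying mean, the test-sample
count k given N is distributed as the normalized product of two NB pmfs.
With equal size factors the unknown mean cancels exactly; with unequal size
factors it is profiled as N/(s_t+s_r).  At dispersion 0 the law is exactly
Binomial(N, s_t/(s_t+s_r)).  Two-sidedness follows the probability-mass rule
of classical exact count tests: p = sum of the probabilities of all splits no
more likely than the observed one (with a 1+1e-12 tie guard).

The conditional weights are computed from a cumulative-log rising-factorial
rather than lgamma differences: `lgamma(k+r) - lgamma(r)` loses ~1e-5 of
precision once r = 1/dispersion reaches 1e10, while the cumulative sum is
stable for arbitrarily small dispersions (the binomial limit is met to 1e-8
over totals ≤ 100 at dispersion 1e-10).

**Size factors.** The default estimator is median-of-ratios (the median over
genes of the count divided by its across-sample geometric mean), not the
total-count ratio.  On the simulated circRNA class — 80 RNAs of which a
dozen are strongly elevated in the reference individual — total-count
factors absorb the regulated genes' signal into the apparent library size
and compress true |log2FC| ≈ 3 down to ≈ 1; median-of-ratios is robust to
exactly this composition bias.  `size_factors(..., method="total")` retains
the simpler estimator.

**Calling rule.** DE means |log2FC| > 1 and raw p < 0.05, both strict;
log2FC is computed on the size-factor-normalized scale with a pseudocount
(default 1).  BH q-values are always reported; `DeParams.use_q` applies the
threshold to q instead, since the source procedure both adjusts p and states
the raw-p rule.  The in-package BH implementation is the step-up definition
(order-preserving, capped at 1) and is cross-checked against statsmodels in
the tests.

## Consensus filter and network assembly

Each reference yields one comparison per other sample (nine for ten trees).
An (RNA, direction) pair enters the consensus set when status = direction in
at least `min_support` comparisons (default 6).  Support is recorded;
raising `min_support` can only shrink the set.

Edges join consensus entries of adjacent layers (ncRNA–miRNA, miRNA–mRNA)
linked by a predicted target pair.  Two direction rules are implemented:

* **same-direction** (default of `assemble_network`, mirroring the source
  procedure): both endpoints must carry the same consensus direction, which
  becomes the edge direction;
* **anti-correlation** (`require_anticorrelation=True`): the miRNA must be
  DE opposite to its target — the behaviour a ceRNA model actually predicts
  — and the edge carries the non-miRNA endpoint's direction.

Because the generator plants a ceRNA-consistent world (ncRNA/mRNA layers
elevated, miRNA layer suppressed in high-VW trees), the pipeline runs the
anti-correlation rule by default; the same-direction rule is exercised by
unit tests on hand-built consensus sets.  Edge support defaults to the
minimum of the two endpoint supports (conservative, monotone in both);
`support_mode="joint"` instead counts comparisons where both endpoints are
simultaneously DE.

Key miRNAs are ranked by degree (distinct consensus neighbours across both
adjacent layers), ties broken lexicographically so rankings are reproducible;
the selection cutoff (top-k or a degree threshold) is a parameter because no
canonical cutoff exists.  Core miRNAs are the intersection of the key lists
of the lncRNA- and circRNA-based networks.

## Correlation screens

Pearson correlation with a two-tailed p from the t-transform on n−2 degrees
of freedom (Spearman available).  Screens use strict raw thresholds —
|r| > 0.8 and p < 0.01 between RNA classes, |r| > 0.6 and p < 0.05 against a
trait — with no multiple-testing correction by default, mirroring the
raw-threshold usage of the emulated analysis; `adjust=True` BH-adjusts
within a screen.  The t-based p assumes near-normal marginals: on strongly
skewed raw abundances at n = 10 it is mildly anti-conservative (the null
test in the suite therefore uses Gaussian noise, and practice should screen
log-scale expression).

## lncRNA filtering

Three independent predicates applied in order (order changes only the
attribution of removals, never membership): FPKM ≥ 0.5 (boundary retained);
summed exon length ≥ 200 bp AND ≥ 2 exons (the conventional lncRNA
definition; the opposite reading of "short and single-exon" is available as
`short_rule="both"`); genomic span clear of every annotated gene's ±1 kb
flank (strand-agnostic).  Interval logic is half-open 0-based internally and
converts at the GTF boundary (1-based inclusive).  Coding-potential
filtering is consumed as a pre-computed id blacklist, not recomputed.

## SNP statistics

MAF is allele-count based over called genotypes (missing calls leave the
denominator; half-calls contribute one allele); the filter keeps MAF ≥ 0.1
inclusive.  Transitions are {A,G} and {C,T}; types are orientation-free
("A/G" covers A→G and G→A).  Frequencies are reported to 2 decimals and the
Ts/Tv ratio both unrounded and to 2 decimals; an all-transition table flags
an infinite ratio rather than dividing by zero.

## qPCR

ΔCt = mean replicate Ct(target) − mean of the reference genes' mean Cts
(arithmetic mean of Cts = geometric-mean normalization on the linear scale);
ΔΔCt subtracts the calibrator sample's ΔCt, and relative expression is
2^−ΔΔCt, so the calibrator is exactly 1.  Per-reference-gene profiles are
available alongside the combined estimator.  The calibrator sample is an
explicit argument (the pipeline uses the lowest-VW individual).

## Target scoring

A gapless stand-in for dedicated plant-target predictors: per-position
penalties (+1 mismatch, +0.5 G:U wobble) doubled at miRNA positions 2–13,
slid over each transcript; pairs with best-window penalty ≤ 4.0 (the
conventional plant small-RNA stringency) are emitted.  No bulges, no
thermodynamics; precomputed target maps can always be supplied instead.

## Synthetic data: what it emulates and what it does not

Defaults: 10 samples; 300 mRNAs, 200 lncRNAs, 80 circRNAs, 60 miRNAs
(desk-scale stand-ins for the tens of thousands in a real transcriptome);
4 planted ceRNA triples per ncRNA kind sharing 4 mediator miRNAs, the first
("hub") with 2 extra mRNA targets per kind; 8 extra DE RNAs per class;
5 trait-tracking mRNAs; planted effect 3 log2 units; NB dispersion 0.05;
log2 noise SD 0.1; Ts/Tv target 1.58 over 5000 sites with 20% of sites below
the MAF filter; 40 decoy target pairs among non-DE RNAs; 3 qPCR replicates
with 0.15-cycle noise.

Phenotypes decline roughly linearly over sample rank (HT 18→8 m,
DBH 30→10 cm, 3% jitter) and the extremes are forced to the ends; VW is
computed exactly from HT and DBH.  The planted expression effect is weighted
by `((VW-min)/(max-min))^4`: concentrating the effect on the extreme
individual is what makes a planted RNA DE in ~9 of 9 pairs against that
reference, the pattern the consensus filter is built for.  Planted
regulators' baseline mean counts are floored at 2^8, reflecting that real
key regulators are reported at FPKM/TPM > 5 — without the floor a planted
RNA can land where no exact test has power.  Each generator draws from its
own RNG stream spawned from the master seed, so adding one simulation never
perturbs another, and equal configs give byte-identical files.

The generator does **not** emulate: read-level artifacts (mapping bias, GC
effects), correlated co-expression modules beyond the planted structure,
linkage between SNPs and expression, tissue differences (one tissue-mixed
matrix is emitted, matching how the libraries were pooled; per-tissue
phenotype correlations are out of scope), or miRNA family structure.  A
green end-to-end test therefore establishes that the pipeline's logic
recovers planted structure under its own model assumptions — not that the
statistical calls are robust to real-data artifacts.

## Numerical and design notes

* Exact-test p-values cached per pair total within a comparison (the
  conditional law depends on the total only).
* The type-I bound in the suite (α + 3 binomial SE over 20 seeds) holds even
  though the generator adds log-normal noise on top of the NB draws — the
  discrete two-sided exact test is conservative enough to absorb the small
  extra dispersion.
* Empty networks, empty SNP tables and constant qPCR genes are handled as
  explicit degenerate cases (empty edge lists, an `is_empty` table marker,
  a per-gene error map) rather than exceptions that abort a run.
* The pipeline manifest contains no timestamps; identical seed + config give
  identical manifests, and every reported total is re-derivable from the
  stage artifacts on disk.
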