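# Methods

## The scan model

Each locus carries one log2(HpaII/MspI) ratio per sample. For a matched
design with k case/control pairs, the scan forms the within-pair
differences d_1..d_k (case minus matched control), and tests

&nbsp;&nbsp;&nbsp;&nbsp;t = mean(d) / (sd(d) / sqrt(k)),&nbsp;&nbsp; p two-sided from t(k−1),

per locus, over the pairs with both members observed. Loci with fewer
than two complete pairs get missing statistics. Zero-variance loci split
into two cases: all differences exactly zero yields t = 0, p = 1; a
constant nonzero difference leaves the t reference undefined, so the
locus is flagged `degenerate` with missing p rather than an artificial
p = 0 — reported p-values always lie in (0, 1].

Methylation states use the zero-ratio rule with strict inequalities:
ratio < 0 methylated, > 0 hypomethylated, exactly 0 a `boundary` call
that state-change summaries exclude. This keeps the call deterministic
without inventing a tolerance around zero.

## Permutation calibration

The genome-wide cut is calibrated on a relabeled null: re-run the scan
under permuted group assignments and take the largest "round" threshold
(ladder 5·10^−k, 10^−k) strictly below the smallest p-value any locus
attained in any permutation. Two schemes are provided:

* `within_pair_flip` — independently swap case/control within each pair
  (sign-flip the paired differences). With k pairs there are 2^k
  patterns; when 2^k − 1 ≤ n_perm all non-identity patterns are
  enumerated.
* `full_relabel` — shuffle subjects into two pseudo-groups of the
  original sizes and re-run an unpaired equal-variance scan.

A subtlety dictates how these are used. For a two-sided statistic the
global sign flip (all pairs swapped) — and, under relabeling, the exact
complement assignment — reproduces the observed |t| at every locus. A
null containing such a pattern always ties the observed minimum p, and a
threshold "below every permuted p" would then exclude every locus by
construction. Sampled nulls therefore exclude the identity and its
mirror; the exhaustive within-pair enumeration (which by its stated
contract contains the global flip) is intended for per-locus permutation
p-values — fraction of the 2^k sign patterns, identity included, with
|t| at least the observed — not for threshold calibration. Calibrate
with a sampled within-pair null (large k) or `full_relabel`.

No FDR adjustment is applied on top of the permutation calibration; an
FDR column can be added to reports but plays no role in tier selection.

## Ranking score

Candidates are additionally ordered by a fold-change-weighted score

&nbsp;&nbsp;&nbsp;&nbsp;score = |mean(d)| / (sd(d) + s0),

with s0 defaulting to the median of sd(d) across loci. Relative to the
t statistic this damps loci whose tiny variance inflates t despite a
negligible mean shift, and promotes loci with large shifts — the
moderated-t idea used purely as an ordering, never as a probability.
With s0 = 0 the score is scale-invariant like t; s0 > 0 is what makes
doubling a mean shift increase the score. Both the spread and s0 zero is
reported as +inf (ranked first) and logged.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes, with
ground truth returned for every locus:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 10,000 | fragments along chr1 (chrX for sex-linked loci) |
| `n_pairs` | 5 | matched case/control pairs |
| `frac_differential` | 0.01 | planted differential fraction |
| `effect_mean`, `effect_sd_across_loci` | 0.60, 0.20 log2 units | per-locus |shift| distribution; sign random, applied to cases only |
| `noise_sd` | 0.32 log2 units | independent per-measurement noise |
| `baseline_means`, `baseline_sds`, `baseline_weight` | ±2.0, 0.6, 0.5 | two-Gaussian bimodal baseline (methylated / hypomethylated modes) |
| `gender_shift` | 2.0 | optional shift on chrX loci in males |

The ±2.0 bimodal baseline is a fixture choice reflecting the empirical
bimodality of HELP ratios around the zero-state threshold; its exact
shape is not load-bearing for any downstream statistic. The shift is
applied to cases only with a random sign (real cohorts show both hyper-
and hypomethylation). The linked bisulphite table maps ratios through a
decreasing logistic link, percent = 100·logistic(slope·(x − midpoint))
with slope < 0, plus clamped Gaussian noise — so the two platforms are
inversely related by construction, as on the real instruments.

What the generator does **not** model: probe-level intensities, dye
bias, fragment-length effects, spatial correlation along the genome, or
locus-specific variance. Passing tests therefore demonstrate the
statistical machinery under the assumed sampling model, not robustness
to array artifacts upstream of the ratio matrix.

With the defaults, pairwise inter-sample Pearson correlations land above
0.97 (the bimodal baseline dominates shared structure); the calibration
tests assert the weaker R > 0.85 band that also covers real-data
variability. Under `frac_differential = 0` the scan's p-values are
uniform (KS-tested at the 1% level at 10^4 loci).

## Normalization and QC

Quantile normalization maps each sample's order statistics onto the
across-sample mean of order statistics; ties receive the mean of the
target values the tied group spans, making the transform deterministic
and exactly rank-preserving. Loci with any missing value are dropped
first (count logged) — the simplest defensible rule, since NA-aware
quantile schemes change the target profile per sample. Centering is per
sample; the median is used (configurable to mean), being the more robust
choice where the convention is unrecorded. Ward clustering runs on
Euclidean distances between sample columns via scipy's
minimum-variance linkage; merge heights are non-decreasing and the tree
is serialized as Newick.

## Annotation

Overlap flags use half-open intersection (≥ 1 bp) against each track.
Gene mapping: a locus is a promoter (PRO) hit for a gene when it
intersects the strand-aware window [TSS − 10 kb, TSS) — the TSS base
itself belongs to the body, avoiding double counting; mirrored on the
minus strand. Gene-body (GB) hits take precedence over PRO for the same
gene; promoter hits on two or more opposite-strand genes make a
bidirectional promoter (PRO2). Enrichment uses the exact right-tailed
hypergeometric tail, reported as −log10 p; the universe size is an
explicit argument, since any knowledge-base-dependent default would be
arbitrary. The CG-cluster and conserved-element definitions themselves
are consumed as user-supplied BED tracks, not recomputed.

## Power machinery

The planning model draws n cases from Normal(delta, sigma) and n
controls from Normal(0, sigma) per informative locus, with delta = 0.60
and sigma = 0.32 taken from the effect-size estimation step
(mean/SD of |difference| over the top-1000 ranked loci). The test is the
**unpaired** two-sided equal-variance t-test: the model specifies
independent case and control distributions, and only the unpaired form
reproduces the small-n behaviour of the tabulated grid (the paired
t with k−1 degrees of freedom does not).

Two routes must agree: Monte Carlo (p-values from the t distribution
inside each replicate; default 2·10^5 replicates, binomial SE ≤ 0.0011)
and the exact noncentral-t tail with df = 2n−2 and noncentrality
delta/(sigma·sqrt(2/n)). The noncentral tail is evaluated by numerical
integration of the chi-square mixture representation
P(T′ > t) = E_V[Φ̄(t·sqrt(V/df) − ncp)], V ~ χ²(df), with quad at
relative tolerance 1e−10 over the region carrying the chi-square mass;
this stays accurate across the whole grid, including large
noncentralities at alpha = 10^−10. Power is monotone in n and in alpha,
and the recommendation helper returns the smallest tabulated n reaching
a target power at a given alpha (0.90 at 10^−5 → 25 per group under the
defaults).

## Problem sizes and numerical choices

Test and analysis runs use 2·10^3–10^4 loci, 5–25 pairs, and 30–255
permutations — sizes at which every statistic here is already in its
asymptotic regime while keeping runs interactive; the same code scales
to ~10^6-locus matrices by virtue of being vectorized per column. The
pipeline derives per-stage seeds from one global seed by CRC-hashing the
stage name, so one integer reproduces a full run; all randomness flows
through numpy Generators. Two-sided p-values are floored at the smallest
positive double so that p ∈ (0, 1] holds exactly.

## Known limitations

* Locus-level only: no region/DMR segmentation or smoothing across
  neighbouring fragments.
* No covariate adjustment in the scan (gender/ethnicity enter only
  through the matched design and the sanity-check comparisons).
* Power model assumes equal variances and equal group sizes; no
  multiplicity-adjusted (FWER/FDR) power curves.
* The candidate report reproduces positional annotation and enrichment
  scores; molecular-interaction network construction around candidates
  depends on commercial knowledge bases and is out of scope.
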