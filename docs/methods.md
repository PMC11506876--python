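# Methods

## Spectra and segmentation

A k-mer spectrum is obtained by sliding a window of length k one base at
a time along the **forward strand only**. No reverse-complement
canonicalization is applied: the A-rich and T-rich tandem-repeat
families must remain distinguishable, which is impossible once k-mers
are collapsed with their reverse complements. Words are indexed
lexicographically with A<C<G<T, fixed package-wide.

Windows containing N are skipped and excluded from the normalizing
total, so assembly gaps and masked bases do not distort frequencies. A
segment whose N-free window count falls below `min_valid_fraction`
(default 0.5) of the possible windows is flagged invalid and excluded
from the reference, from quantile calibration and from every
correlation.

Chromosomes are cut into consecutive, non-overlapping segments of equal
size; the trailing remainder is dropped rather than producing one
shorter segment with different count support. The segment size must be
at least 4^k so each word can expect some counts. The word-size rule
k = round(0.7·log₄(n)) uses round-half-up (not banker's rounding) so the
mapping from length to k is monotone; at n = 40,000 it gives k = 5.

The chromosomal reference spectrum is the **unweighted mean of the valid
segment spectra**, not the pooled whole-chromosome count vector. This
centers the deviation statistic on the segment ensemble (the mean
deviation is then a genuine dispersion measure); for gap-free
chromosomes with equal-size segments the two choices differ negligibly.

## The deviation statistic

For word set S:  d_S = 100 · Σ_{i∈S} |f_local,i − f_ref,i| / Σ_{i∈S} f_ref,i.

Absolute differences are used: a signed sum of frequency differences is
identically zero for normalized vectors. With S = all words the
denominator is 1 and d is the L1 distance × 100, in [0, 200]. Restricted
sets are normalized by the reference mass of the set, which puts the
overall track and the word-set tracks on one percent scale and lets
word-set deviations exceed several hundred percent when a family is
locally amplified. This normalization is isolated in one function
(`spectrum_deviation`) so an alternative convention can be swapped in.

The all-pairs alternative (mean Pearson correlation of each segment's
spectrum with every other segment's) is implemented as
`pairwise_peculiarity` and kept as a cross-check: on synthetic
chromosomes with planted deviant regions of mixed repeat composition the
two tracks correlate at about −0.9.

## G+C correction

`gc_correct` fits d ~ a + b·gc by ordinary least squares over valid
segments and subtracts b·(gc − mean gc). The residual is re-centered on
the original mean so quantile thresholds remain comparable between raw
and corrected tracks. Linear removal is the minimal model for "corrected
for local G+C content"; no higher-order trend is fitted. Constant G+C is
a warned no-op.

## ReDFAS calling and classification

The threshold is the nearest-rank empirical quantile (default 0.95) of d
over valid segments, **per chromosome**; flagging uses strict
inequality, which guarantees at most 5% flagged under ties (a
genome-wide threshold can be emulated by concatenating tracks before
calling). Runs of flagged segments are merged into regions, optionally
bridging up to `merge_gap` unflagged segments (default 0). Classes:
overlap with the supplied centromere interval → centromeric (takes
precedence); within `subtelomere_margin` (default 2 Mbp, scaled down for
small synthetic chromosomes) of either end → subtelomeric; otherwise
intermediate. The labels are positional conventions, not statistical
claims.

PCA of the per-segment spectra is computed on centered, unscaled
frequency vectors (scikit-learn, full SVD); component signs are fixed by
making each component's largest-magnitude loading positive.

## Hi-C summaries and bootstrap significance

Per-segment contact level is the mean of the segment's matrix row over
valid, unmasked bins, excluding the diagonal (self-contacts dominate and
carry no between-locus information). Bins with all-zero rows are invalid
from the file side; centromeres or other regions are masked by interval.
Matrices are taken as provided; no ICE/coverage normalization is applied.

`bootstrap_correlation` draws, in each of `n_reps` = 100 repetitions,
`n_sample` = 100 jointly valid segments **without replacement** and
computes a Pearson correlation; the reference repeats this after
independently permuting one track across segments in every repetition,
which destroys the pairing while preserving both marginals. Significance:
|mean_emp − mean_ref| > √(σ²_emp + σ²_ref). Under independence the
reference has mean ≈ 0 and spread ≈ 1/√(n_sample − 1) ≈ 0.10. Comparing
two correlation results (e.g. two cell lines) uses combined standard
errors √(σ²_a/n + σ²_b/n) with n the number of correlated samples per
repetition, strict inequality. All sampling requires an explicit seed.

## Enrichment

Coverage and content fractions are computed on merged interval unions
(base-weighted; breakpoint *regions* count by their bases, not as
points). The significance null places each breakpoint interval's start
uniformly at random so the interval fits on the chromosome — length
preserved, mutual overlaps permitted — `n_perm` = 1000 times, and
reports (observed − null mean)/null sd. A permutation null was chosen
over a binomial approximation because it respects interval lengths and
feature fragmentation exactly; a feature union covering the whole
chromosome leaves the null degenerate (σ = 0) and the z-score undefined.

## Synthetic data: what it emulates, and what it does not

`generate_chromosome` draws an i.i.d. background with P(G)+P(C) equal to
the target G+C (default 0.41, human-like) and overwrites, inside each
planted region, about `excess_fraction` of positions with blocks of six
tandem copies of words drawn from the chosen word set. Two standard
layouts are provided: `demo_chromosome` (2 Mb, 10 kb segments, one
AT-rich and one GC-rich 50 kb region at excess 0.5 — exactly the 5%
segment budget the default quantile can flag, used for recovery tests)
and `heterogeneous_chromosome` (six 40 kb regions, one per built-in
family — a repeat landscape of mixed composition, used for the
pairwise-vs-reference comparison).

`generate_contacts` builds values[i,j] = (1+dist(i,j))^(−α) ·
exp(coupling·(z_i+z_j)/2) · lognormal noise, with α = 1 (canonical
polymer-scaling decay) and z the standardized deviation track. Two
deliberate modelling choices keep the coupling coefficient the *only*
driver of track-level correlation: dist is the circular bin distance
min(|i−j|, n−|i−j|), because a linear distance imposes a deterministic
edge gradient on per-bin mean contacts that correlates with any
spatially structured track even at coupling 0; and the lognormal noise
(default σ = 0.5) has a per-bin visibility component in addition to the
per-entry component, because purely per-entry noise cancels when
averaging hundreds of bins and would leave the per-bin means a noiseless
function of z, saturating the correlation at any nonzero coupling. With
these choices the correlation response is monotone in the coupling
(≈ 0.0 / 0.66 / 0.90 / 0.93 at coupling 0 / 0.3 / 0.6 / 1.0) and the
coupling-0 null is calibrated.

`generate_breakpoints` places each interval fully inside a planted
region with probability p = c(fold−1)/(1−c) (c = planted coverage) and
uniformly otherwise, so the expected base-fold over coverage equals the
target; fold < 1 instead forces a share 1−fold of placements outside.

What the generator does **not** emulate: real repeat-family sequence
models (Alu/L1), first-order or higher Markov background structure,
isochore-scale G+C variation, TADs/compartments in the contact model,
and diploidy. Passing tests therefore demonstrate that the statistics
recover signals of the planted kind at realistic sizes and noise levels,
not that the pipeline's thresholds are optimal for real genomes.

## Problem sizes and numerical choices

Tests and the acceptance script use 2–6 Mb chromosomes at 10 kb
segments (200–600 segments, k = 5), 100–1000 permutations, and 100×100
bootstrap repetitions — the same segment-count regime as a human
chromosome at 40 kb resolution, scaled in physical length. Quantiles
use the nearest-rank definition; ties are broken conservatively (strict
inequality, nothing flagged when all values tie). Frequencies of valid
spectra sum to 1 within 1e-12; degenerate inputs (all-N segments,
zero-variance spectra, zero reference mass, σ = 0 nulls, constant G+C)
are flagged as undefined rather than raised, except where no meaningful
result exists at all (empty FASTA, no valid segments).

## Known limitations

* The percent normalization of word-set deviations (by reference set
  mass) is one of several defensible conventions; it is isolated behind
  one function.
* The per-chromosome 95% threshold makes region counts depend on
  chromosome heterogeneity; a genome-wide threshold changes calls.
* `pairwise_peculiarity` is O(n²·4^k) and intended for validation, not
  for whole-genome scans.
* The contact-matrix loaders accept two plain-text dialects; binary
  .cool/.hic files must be converted upstream.
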