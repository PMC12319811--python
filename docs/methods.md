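# Methods

This note documents the models and procedures implemented in `dyadsync`,
the choices made where the underlying analysis admitted more than one
reasonable reading, and what the synthetic validation does and does not
establish.

## Inter-subject trajectory similarity (ISTS)

For one subject, one region of interest (ROI), the multi-voxel pattern
(MVP) at TR *t* is the vector of voxel signals at that time point. The
**pattern trajectory matrix** is the T×T matrix of Pearson correlations
between MVPs at every pair of TRs; it characterizes how the region's
spatial pattern evolves, independent of overall response amplitude.
**ISTS** for a dyad (a married couple, or a random male–female pairing) is
the Pearson correlation between the two members' vectorized trajectory
matrices, computed per ROI.

Numerical conventions:

- Vectorization uses the strict upper triangle, diagonal excluded. The
  diagonal is identically 1 and would only inflate similarity; for a
  symmetric matrix the upper triangle is information-preserving.
- A TR whose MVP is constant across voxels has no defined correlation;
  its row/column is set to missing with a warning, and ISTS treats
  missing entries pairwise-complete. Fewer than 3 usable entries yields a
  missing ISTS rather than an arbitrary number.
- Condition-restricted ISTS (e.g. marital-scene TRs only) masks TRs
  *before* building the trajectory matrix, so only within-condition
  temporal structure is compared — the masked TRs form their own
  stimulus stream rather than leaving holes in a longer one.
- Random pairs are a **derangement** of the couples: a seeded
  rejection-sampled permutation of wives with no fixed points, so no one
  is paired with their own spouse and no one is reused. A single draw is
  the default; averaging over several draws is available
  (`make_random_pairs(..., n_draws=k)`).
- **ISTS-Z** z-scores ISTS per ROI across all dyad classes pooled
  (high-satisfaction couples, low-satisfaction couples, random pairs),
  sample SD (ddof=1). When the analysis spans two scanning states (movie
  and rest), normalization is done within state; the alternative
  (pooling states) was rejected because state-level mean differences
  would otherwise masquerade as dyad-level variation.
- Whole-brain ISTS is the unweighted mean over ROIs, skipping missing
  entries and recording the contributing count.

## Ordered-state HMM event segmentation

Naturalistic viewing evokes a sequence of temporally stable multivariate
patterns ("events") punctuated by rapid transitions. The segmentation
model is a hidden Markov model over K ordered states with the no-return
constraint: from state k the chain stays at k or advances to k+1. Each
state is therefore one contiguous event.

Model details (`EventSegmenter`):

- **Features.** A network's feature series is the TR × n_ROIs matrix of
  voxel-mean ROI signals (a voxel-level option exists). ROI means were
  chosen as the default because event structure in this model lives in
  the relative activation of regions within a network, and the
  desk-scale voxel counts add noise without adding structure.
- **Normalization.** Features are z-scored per TR (each time point's
  pattern has mean 0, SD 1 across features) before fitting, so states
  capture pattern shape rather than global amplitude. Per-feature
  z-scoring is available as an option.
- **Emissions.** Isotropic Gaussian around each state's mean pattern
  with one shared variance, updated in the M-step. This is the minimal
  emission model under which "a distinct mean pattern per event" is
  identifiable at desk scale.
- **Transitions.** Fixed, not learned: advance probability K/T (K
  expected events in T TRs), last state absorbing, chain pinned to start
  in state 1. Likelihoods are totals over all monotone state paths
  (forward algorithm in log space); no end-state constraint is imposed.
- **Fitting.** EM with deterministic initialization (states tile the run
  into K equal contiguous blocks), convergence at relative
  log-likelihood change < 1e-6 or 200 iterations. Training
  log-likelihood is non-decreasing across iterations (asserted in
  tests to 1e-9).
- **Assignment.** Per-TR argmax of the marginal posterior, forced
  non-decreasing; boundaries are the TRs where the assigned state
  increments. Viterbi decoding was not used; on clean data the two
  differ by at most a TR, and the marginal-posterior convention matches
  the established event-segmentation toolboxes.
- **Uneven events.** An optional post-EM refinement (off by default)
  proposes merging the two most similar adjacent states while splitting
  the segment with the largest residual variance, re-runs EM, and keeps
  the proposal only if the training log-likelihood improves.

**Model selection** is nested cross-validation: the outer loop holds out
one test subject; the remaining subjects are shuffled (seeded) into a
train set and a validation set, each averaged across subjects; the inner
loop fits every candidate K on the train average and scores the
validation average by forward log-likelihood. The fold's K* maximizes
validation likelihood; the overall K* is the mode across folds, ties
breaking toward fewer events. The study-scale scheme (27 train / 8
validation, K from 1 to 100) is expressible directly; the desk-scale
default is 8 train / 3 validation with K from 1 to 10 and an optional
subsample of outer folds, sizes chosen so that simulation studies with a
dozen subjects remain informative.

## Within-event ISTS

Given an event segmentation — by default fitted to default-mode-network
(DMN) activity pooled over all couples — or a movie-clip table, ISTS is
recomputed inside each window: trajectory matrices are built from the
window's TRs only, correlated within the dyad, and averaged across
windows (unweighted by default; length-weighted available). Windows
shorter than 3 TRs produce a single off-diagonal element and no usable
correlation; they are skipped and counted. The dyadic correlation is
taken over each window's trajectory matrix, not over each window's mean
pattern: the trajectory reading follows the pipeline's definition of
similarity as correlated pattern *evolution*; the mean-pattern variant
is a different quantity and is deliberately not implemented.

A point worth noting for interpretation: windows that straddle an event
boundary contain a pattern switch that is shared by *all* subjects
viewing the same stimulus, which inflates raw ISTS for couples and
random pairs alike. The couple-specific quantity — the couple-vs-random
ISTS advantage — is what within-event analysis sharpens, and that is the
property the test suite asserts.

## PLS-1 inference

The region-wise link between ISTS and satisfaction is the first partial
least squares component: the unit vector **w** over ROIs maximizing
cov(X**w**, y) for the dyad × ROI ISTS matrix X (column-centered) and
dyad-level satisfaction y. For a single component this is closed-form,
**w** ∝ Xᶜᵀyᶜ; the sign is fixed so the component score correlates
non-negatively with y. Raw ISTS enters by default (the z-variant is a
flag), and the satisfaction target is the couple-mean score carried by
the dyad table.

- **Permutation test** (default 5,000 permutations): y is shuffled
  across dyads; the statistic is the squared covariance of the first
  score with y; p uses the add-one formula (1 + #{null ≥ observed}) /
  (1 + n_perm), so p is never 0. Under the null the rejection rate at
  α = 0.05 is calibrated (checked at 500 datasets × 200 permutations).
- **Bootstrap** (default 500 resamples): dyads resampled with
  replacement, PLS-1 refitted, each bootstrap weight vector sign-aligned
  to the original (PLS components are sign-indeterminate; without
  alignment the SE estimates are meaningless). z = w / SE_boot per ROI,
  normal-theory CIs, two-tailed normal p.
- **FDR**: Benjamini–Hochberg at q = 0.05 across ROIs.

Group contrasts use Welch two-sample t tests (two-tailed) with pooled-SD
Cohen's d, a two-way type-II ANOVA for the scanning-state × marital-status
design (the status factor may carry two or three levels; both the
couples-only 2×2 and the 2×3 with random pairs are supported), and
Pearson/Spearman correlations for satisfaction and marriage-duration
analyses.

## Synthetic data generator

The generator provides ground truth for every downstream stage. Per ROI,
each spouse's voxel × TR signal is

    x(t) = mu[event(t)] + sqrt(c)·s(t) + sqrt(1−c)·e(t) + n(t)

with K event mean patterns `mu` (shared by all subjects, as a common
stimulus would impose; separation set by `event_contrast`), a
couple-shared fluctuation `s` and an idiosyncratic fluctuation `e` (unit
variance, smoothed with a 3-TR moving average and rescaled, to mimic
BOLD autocorrelation), white noise `n`, and coupling strength c ∈ [0,1]
per couple. Satisfaction scores are 60 + slope·(c − mean c) + noise,
classed high/low at the 60-point threshold, so the coupling →
satisfaction effect is known and monotone. Random pairings use the same
derangement operation as the real pipeline.

Defaults are the desk-scale study conditions used throughout the tests:
30 couples, 20 ROIs, 50 voxels/ROI, 100 TRs, 5 events, coupling drawn
uniformly in (0.2, 0.8), `event_contrast` 1.0 and `noise_sd` 1.0 (event
structure, fluctuations and noise on a common unit scale),
satisfaction slope 40 and noise SD 5 (score spread ≈ ±15 around the
threshold with meaningful but imperfect coupling correlation). Strong-
signal event-recovery settings raise `event_contrast` to 5. Effect
sizes were chosen for test power, not realism — the human study reports
no generative effect sizes to emulate.

What the generator does **not** emulate: hemodynamic convolution, head
motion, scanner drift, spatial correlation between voxels, ROI-specific
event timing, or heterogeneous event structure across couples. Passing
the recovery tests therefore shows the estimators are correct and
well-calibrated under the assumed generative family, not that the
pipeline's effect sizes transfer to real fMRI.

## Problem sizes

The validation suite runs at: 20 replicates × 3 coupling levels of
30-couple cohorts for coupling recovery; 10 seeds of 12-subject cohorts
for boundary recovery, nested-CV selection (4 outer folds) and group
K-ordering (3 outer folds); 500 null datasets × 200 permutations for
calibration; 10 end-to-end runs at generator defaults, where the DMN
segmentation driving the within-event stage is fitted at the generator's
event count rather than re-selected by nested CV in every run. Oracle
checks use
50 random trajectory instances (T ≤ 12, V ≤ 10) and 100 exhaustive-
enumeration HMM instances (T ≤ 6, K ≤ 3).

## Known limitations

- The HMM emission model is isotropic with one shared variance; strongly
  heteroscedastic features would need the per-feature normalization
  option or a richer emission model.
- The advance probability is fixed at K/T, never learned; event-length
  priors other than this implicit geometric one are not expressible.
- Random-pair nulls use one derangement draw by default; the sampling
  variability of that draw is visible at small n (use `n_draws` > 1).
- `two_way_anova` assumes a between-dyads design; repeated-measures
  structure (the same couple in both scanning states) is not modelled.
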