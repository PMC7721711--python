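# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `wmdecode`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Designs

Both tasks are generated as TR-indexed trial tables (TR = 0.46 s, indices
1-based, intervals inclusive). The localizer presents each of the 54 images
once per run in subcategory triplets: 13-TR instruction screen, trials of
3 TRs + a jittered ITI drawn uniformly from {5..10} TRs, and a 13-TR
fixation after each triplet (18 triplets/run). The study task has 40-TR
fixation blocks at both run edges and trials of 6-TR image + 6-TR operation
screen + {5..9}-TR ITI, 12 trials per operation per run, 4 per
operation x category. Item-to-operation assignment cycles seeded
permutations of each category's 18 exemplars, so with >= 5 runs every
exemplar serves every operation at least once; no further balancing is
imposed. Replacement items are drawn from a different category
(replace-category) or a different subcategory of the same category
(replace-subcategory). Sequence optimization for BOLD deconvolution is
deliberately replaced by seeded shuffling: ordering optimality affects
estimator efficiency, not the correctness of any statistic tested here.

The replace-subcategory condition is generated but excluded from the main
analyses at label-construction time (the `classes` argument), never at
design time.

## The generator

One simulated brain is a 3-D lattice (default for tests and acceptance runs:
12 x 12 x 12; the class default is 14 x 14 x 14) with an ellipsoidal mask,
hemispheres split at the mid-x plane, and a contiguous posterior-ventral
block tagged as a ventral-visual-stream-like (VVS) region. Patterns:

- **Category patterns** occupy three contiguous slabs of the VVS block with
  *positive* unit-norm activations. Contiguity and positivity are what make
  one-sided contrasts and 10-voxel cluster correction behave as they do on
  real data, where category-selective cortex is a spatially coherent
  activation. An `overlap` parameter shares a random voxel fraction between
  categories; at 0 the supports are disjoint and cross-category patterns are
  exactly orthogonal.
- **Subcategory and item patterns** are signed unit-norm Gaussians on their
  category's support.
- **Operation patterns** are signed unit-norm Gaussians on the non-VVS
  voxels, mirroring the frontoparietal origin of operation information and
  keeping control signals out of the category decoder's voxel support.

Default amplitudes a_cat = 1.0 >= a_sub = 0.5 >= a_item = 0.35, a_op = 0.8,
noise sigma = 0.6 (i.i.d. Gaussian per TR and voxel). At these values a
2-run localizer decodes category at ~0.6–0.65 accuracy and subcategory just
above its 1/9 chance — the qualitative regime of real data, where category
decoding is strong and subcategory decoding weak.

**Time course.** Stimulus components are active during the presentation
epoch. In the localizer the representation persists through each trial's ITI
and, after the third triplet trial, through the 13-TR fixation — the
sustained "mini-block" that the 31-TR boxcar labels and GLM regressors
assume. In the study task, components decay from operation onset with
operation-specific exponentials (half-lives in TRs):

| operation | item half-life | category half-life | onset delay | replacement rise |
|---|---|---|---|---|
| maintain | inf | inf | – | – |
| replace (both) | 1.5 | 1.5 | 0 | 1 − exp(−0.5 t) |
| clear | 2.5 | 2.5 | 0 | – |
| suppress | 4 | 30 | 6 TRs | – |

Replace removes fastest while the replacement item's components rise;
clear is intermediate; suppress spares the coarse category signal almost
entirely while the item-specific component decays late. The generator's
operation pattern stays on through the operation screen and fixation. These
half-lives are free parameters of the generator (the real experiment
*measures* such dynamics, it does not report them); the defaults were chosen
once so that the planted ordering replace < clear < suppress of the
maintain-relative category-evidence drop is recoverable by the full decoding
chain at the validation scale (8 subjects x 2 runs), and they are recorded
in every pipeline manifest.

**Proactive interference.** When trial N+1's category matches trial N's, all
of trial N+1's stimulus components are scaled by a multiplier keyed to trial
N's operation: 0.3 for maintain/replace/clear (a lingering or recently
removed same-category item impairs new encoding) and 1.7 for suppress
(planting the empirical signature that suppression spares, even aids,
related encoding). The magnitudes are again chosen once for recoverability
of the sign pattern and the suppress-vs-others contrast at 8 subjects x
2 runs; their scientific content is the *sign pattern*, not the numbers.

**Hemodynamics.** Default lag mode is a pure 10-TR delay, exactly matching
the 10-TR label shift used by all analyses, so recovery tests are not
confounded by response-shape mismatch. An `hrf` mode convolves with a
double-gamma response (peak 6 s, undershoot 16 s, ratio 1/6, sampled at
0.46 s) for realism; the GLMs always use that same double-gamma kernel.

**Cohorts.** Every simulated subject receives an independent trial ordering,
as real participants do. This matters: with one shared ordering, the
per-condition imbalance of same-category trial histories (which gate the
interference multipliers) becomes a bias common to all subjects and does not
average out, distorting condition trajectories by up to ±0.1 evidence units.

Censoring is off by default; a configurable fraction of TRs can be flagged
to exercise the masking contract. Physiological noise, motion, and drift are
not modelled.

## Decoding choices

- Voxels are z-scored within run over non-censored TRs before
  classification and pattern analysis.
- "Evidence" is the per-class sigmoid output of the one-vs-rest classifier,
  not softmax-normalized: classes are scored independently in [0, 1].
- The logistic objective is sum of losses + lambda * ||w||^2 / 2, solved by
  scikit-learn's lbfgs (C = 1/lambda, tolerance 1e-6); lambda = 0 is the
  unpenalized fit.
- Stage-1 penalty grid {0, 1, 5, 25, 125, 625, 3125, 10000}; stage 2 is a
  10-point linear grid between the stage-1 winner's grid neighbours; ties
  break toward the smaller penalty.
- Accuracy and AUC are macro-averaged over classes; AUC is the rank-based
  (Mann-Whitney) one-vs-rest statistic with ties averaged; confusion rows
  are normalized within true class.
- Feature selection, penalty scoring, template construction and
  hyperalignment transforms consume training data only; the tests plant
  leak probes (a voxel informative only in the held-out run, a poisoned
  classification half) and assert they cannot influence the fitted objects.

## Trajectory statistics

Blocks are fixed 0-based slices (6,9), (9,12), (12,15), (15,18), (18,21) —
TRs 7–21 inclusive. Baseline correction subtracts each condition's own mean
over TRs 1–6 (idempotent; between-condition differences at any TR change
only by the difference of baselines). "Reliably" below zero / above baseline
means a two-sided one-sample (or paired) t test at p < 0.05 after
Benjamini-Hochberg correction across the five blocks within condition, with
the sign of the mean enforced; the FDR family is per condition (a config
switch could widen it, but per-condition matches the block-test reporting
convention adopted throughout). Subjects are the unit of analysis for every
test.

## RSA choices

- Category selection uses a one-sided target > non-targets t contrast
  (selectivity is directional), cluster-corrected at 10 voxels with
  6-connectivity.
- Item weights are the *signed* LS-A t-contrast values, unthresholded.
- Fisher z = atanh(r) with |r| clipped at 1 − 1e-7; undefined correlations
  (constant vectors) exclude the pair rather than impute.
- Templates are fit once on all localizer runs (no per-fold re-estimation),
  and study patterns are weighted with the probed item's own weights — so
  "related" and "other" similarities each use the respective template's
  weight vector.
- Motion-parameter nuisance regressors are accepted as an optional matrix
  but are not generated (the simulator has no motion).

## Importance maps

Membership follows the sign-agreement rule: a voxel enters an operation's
positive map when its mean z-scored activity over that operation's labeled
TRs and its classifier weight are both positive (negative map: both
negative); disagreeing voxels get exactly zero. Magnitude is the
activity-weight product a_v * w_v. For group maps each subject's map is
normalized by the standard deviation of its combined |importance|
distribution *without* mean-centering: centering the absolute values and
re-signing would flip the polarity of below-average-magnitude voxels, which
contradicts the positive-map/negative-map separation, so scale-only
normalization is used. Maps are averaged, the top 5% of magnitudes kept per
polarity, and 6-connected clusters under 10 voxels removed. Display
smoothing is out of scope.

## Interference statistics

Pairs never span runs; the first trial of each run is untagged. Replace
pairs whose replacement item's category equals the next item's category are
excluded from the main cells and form the "same" cell of the
replace-same-new bootstrap variant. Bootstrap p-values are two-sided
proportion-based with +1 smoothing: p = 2 min(P(D* <= 0), P(D* >= 0)) with
(count + 1)/(n + 1). The RM-ANOVA uses all four operations;
Anderson-Darling normality is reported as a diagnostic, never as a gate.
The Tukey-Kramer comparisons use the studentized-range distribution on the
RM-ANOVA error term.

## Problem sizes

The bundled tests and the acceptance script run at deliberately small scale,
chosen as the smallest sizes at which each planted effect is reliably
recoverable: 12^3 (occasionally 10^3) lattices of ~900 (~500) in-mask
voxels, 2-run designs for decoding and recovery, 5-run localizers where the
five-repetition template structure matters, cohorts of 8 subjects, 100-group
permutation nulls and 1000-iteration bootstraps. The full-size design
arithmetic (5 localizer runs, 6 study runs) is always generated and checked
exactly.

## What passing tests do and do not show

The generator produces linearly decodable, stationary, i.i.d.-noise data
with a hemodynamic response the analyses model exactly (in the default lag
mode). Passing recovery tests therefore demonstrates the *correctness* of
the pipeline — labels land on the right TRs, nothing leaks across folds,
statistics match their closed forms, planted orderings and signs are
recovered — not that the pipeline would reach any particular effect size on
real BOLD data, with its autocorrelated noise, motion artifacts,
HRF variability and non-stationary attention. The chance-calibration suite
(permutation nulls at 1/3, 1/9, 1/5, AUC 0.5) is the part that transfers
unchanged to real data.

## Known limitations

- The simulator's removal dynamics are exponential and deterministic per
  operation; real dynamics may be non-monotonic or trial-variable.
- Subcategory structure is a single signed pattern per subcategory; no
  graded within-category similarity geometry is planted.
- Hyperalignment assumes equal selected-voxel counts per hemisphere across
  subjects (the per-subject top-k lists are truncated to the shortest).
- Behavioral reaction-time analyses of this paradigm are out of scope (no
  behavioral responses are simulated).
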