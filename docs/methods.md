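# Methods

This note documents the models and procedures `intrumem` implements,
the defaults it chooses where the design was genuinely open, and what
its synthetic studies can and cannot show about real data.

## The decoding problem

A participant watches one film run containing `n_scenes` emotional
scenes; a week-long diary then labels each scene, per participant, as
*flashback* (it returned as an intrusive memory for that person) or
*potential* (it intruded for others but not them). The pipeline asks
whether the BOLD signal recorded during viewing predicts the label —
for a *new* participant (across-participant protocol) or for a held-out
scene pair of the same participant (within-participant protocol).
Flashbacks are rare (≈3 of 20 scenes, a ≈5:1 imbalance) and
idiosyncratic, which drives three design choices: cost-weighted
classifiers, sensitivity as the primary metric, and permutation nulls
rather than accuracy baselines.

## Generative model of the synthetic studies

Each of K spatial networks has a unit-norm Gaussian-blob map `s_k` over
the voxel grid and a neural amplitude time course

```
a_k(t) = Σ_scenes (b_k + ε_{p,s,k}) · boxcar_s(t)
       + Σ_{flashback scenes} Σ_w e_k[w] · boxcar_{s,w}(t)
```

with baseline `b_k` (default 10), per-(participant, scene, network)
amplitude jitter `ε ~ N(0, 5²)`, and a window-indexed flashback effect
`e_k[w]`. The voxel signal is `Σ_k s_k · (a_k ⊛ h)(t)` plus i.i.d.
Gaussian voxel noise (SD 1), where `h` is the canonical SPM
double-gamma HRF (peak ≈6 s, undershoot ≈16 s), sampled at TR = 3 s.
The model is linear, so least squares on the known convolved design
recovers every planted amplitude exactly in the noiseless limit — the
main oracle used by the tests.

Defaults defining the canonical desk-scale study: 35 participants,
20 scenes of 10–20 s separated by 12 s (so the 12 s post-scene window
never overlaps the next scene), 12 s lead-in and tail, giving a run of
≈560–580 s (≈190 volumes); grid 20×20×10 = 4000 voxels; 39 networks of
which 3 are predictive with effect 2× the voxel noise SD, each in a
*single* window (cycling initial6 / remainder / post12) — networks
whose involvement is specific to a moment of the scene rather than
sustained. Per-scene intrusion probability 0.15; participants drawing
zero flashbacks are resampled, the analogue of excluding zero-intrusion
participants, which raises the retained-cohort mean count to
`3/(1−0.85²⁰) ≈ 3.12`.

Two generator choices deserve explanation:

* **Amplitude jitter is load-bearing.** Without scene-to-scene
  amplitude variation every network in a run shares the same scene
  boxcar time course, the mixing matrix is rank-1, and no decomposition
  could separate 39 networks. The jitter SD (5, i.e. half the baseline)
  is what places each network's temporal variance above the PCA noise
  floor of the rank reduction.
* **Blob overlap is capped** (pairwise |map dot product| < 0.3, blob σ
  scaled to 15–25% of the smallest grid dimension). Strongly
  overlapping maps violate the spatial-independence assumption the ICA
  relies on; the cap keeps the planted model inside the regime the
  method assumes.

What the generator does **not** emulate: temporal autocorrelation of
the noise, physiological noise and motion, anatomical realism of maps,
multi-run sessions, scene content outside the 20 labelled scenes.
Passing tests therefore demonstrate correctness of the pipeline's
bookkeeping and its statistical behaviour *under the assumed model* —
not that real peri-traumatic BOLD carries a decodable signature.

## Group ICA and back-projection

Temporal-concatenation group spatial ICA: per participant, each
voxel's temporal mean is removed and the block is divided by its pooled
SD (one scalar per participant, so no one dominates); blocks are
stacked along time. The data are reduced to k dimensions by a
randomized SVD (2 power iterations — ample for signals that sit well
above the noise floor) and unmixed with FastICA taking independence
over voxels (tolerance 1e-4, max 500 iterations). Sign and order are
conventions, fixed so each map's largest-|weight| voxel is positive and
components descend by explained variance; the fit is deterministic
given the seed. If the first fit misses tolerance one restart with a
fixed derived seed is attempted; a second failure raises by default.
Requesting more components than the data hold (deliberately done in the
component-count sweep) routinely leaves the surplus noise components
unconverged, so the sweep runs with `on_fail="warn"`.

Participant time courses come from stage-1 dual regression: each volume
is regressed on all group maps jointly (ordinary least squares on the
raw run). Stage-2 (participant-specific maps) is out of scope. When the
generative model holds noiselessly, back-projection is exact.

## Features

A timepoint acquired at `i·TR` belongs to window `[start, end)` iff
`start ≤ i·TR < end`; the half-open rule keeps adjacent windows
disjoint and is TR-exact (6 s = 2 samples at TR 3). The initial window
is capped at the scene offset so that for scenes shorter than 6 s the
initial and remainder windows still partition the scene. A scene whose
remainder window holds no sample reuses the initial-window mean
(keeping the feature matrix rectangular, logged); a scene too short to
hold one sample is an error. No hemodynamic-lag shift is applied to the
windows by default (`lag` exists, default 0): the windows deliberately
measure BOLD in scene-locked time, which is why a neural effect planted
in the first 6 s surfaces in the *remainder* window average — the HRF
ramp is still near zero at t = 0 and 3 s.

## Classifiers

Both families operate on features z-scored with training-fold
statistics and accept a flashback misclassification cost `c ≥ 1`,
defaulting to the training potential:flashback count ratio (inverse
class frequency, floored at 1).

* **LDA**: pooled within-class covariance with analytic (Ledoit–Wolf)
  shrinkage — necessary because 117 features approach the row count of
  a training fold — and effective class priors ∝ count × cost, which
  both weights the covariance pooling and shifts the Bayes threshold
  toward calling flashbacks.
* **Linear SVM**: hinge loss with per-class error costs (C = 1 default,
  solver tolerance 1e-6 so the fit is invariant to row order).

Prediction is the sign of the linear score; an exact zero goes to
flashback, favouring sensitivity. Raising the cost can only move the
threshold toward the flashback side, so training-set sensitivity is
non-decreasing in `c` (property-tested).

The within-participant variant selects voxels by pooled-variance
two-sample t on the training scenes only (top k = 1000 by |t|, ties by
voxel index, NaN statistics from zero-variance voxels treated as 0).
Selection inside the fold is deliberate: selecting on all scenes would
leak the held-out labels.

## Evaluation protocols

**Across participants (LOSO).** One fold per participant. The strict
default refits the group ICA on the training participants of every
fold, so nothing about the held-out run can influence training (a test
asserts the trained fold model is byte-identical when the held-out data
are replaced by noise). A `refit_ica_per_fold=False` flag shares one
cohort decomposition across folds — the cheaper variant used for
fold-structure checks and the component-count sweep, where 3 counts ×
35 folds × ICA refits would be disproportionate. Sensitivity is
undefined for a fold without flashback scenes; such folds are excluded
from the cross-fold mean with a log entry, never imputed. Reported
summaries: per-fold confusion counts, accuracy and sensitivity, their
cross-fold means, and SE = SD/√folds.

**Permutation null.** The decomposition and features are label-free,
so the null shuffles diary labels *within each training participant*
(preserving everyone's flashback count and hence the idiosyncrasy
structure) and refits only the classifier per fold; test labels stay
fixed. 100 shuffles by default. On a no-effect study the observed mean
sensitivity falls inside the null's central 95%; on the planted-effect
study it exceeds the 95th percentile.

**Within participant.** Eligibility requires ≥4 flashback scenes
(configurable) and ≥2 scenes per class; folds enumerate every
(flashback, potential) pair — exhaustive pairing extracts the most from
scarce positives, since the iteration scheme was an open choice. The
report emits both the pooled-over-scenes and averaged-over-folds
accuracy (they coincide when folds are equal-sized, but both are kept
because the distinction matters for unequal designs).

**Component-count sweep.** LOSO is repeated per requested k. On the
canonical study, mean *accuracy* peaks at the true dimensionality
(k = 39) and falls off at k = 5 and k = 70. Mean sensitivity does not
peak there: with 5 components the cost-weighted classifier simply calls
flashback more often (high sensitivity, poor accuracy) — a threshold
trade-off, not better discrimination, which is why the sweep is
summarised by accuracy.

## Numerical conventions and edge cases

* All randomness funnels through integer seeds
  (`numpy.random.SeedSequence`); identical seeds give bit-identical
  studies, decompositions and reports.
* Window membership uses a 1e-9 tolerance against floating-point
  boundary error; schedules validate strict onset ordering,
  non-overlap and run fit, naming the deficit when a fixed run is too
  short.
* ICA component counts are validated against `min(T, V)` and against
  the numerical rank of the reduced spectrum; collinear spatial maps
  make the dual-regression design singular and raise.
* Problem sizes throughout (4000-voxel grids, ≈190-volume runs,
  35-participant cohorts, 100-shuffle nulls) are chosen so any single
  analysis completes in seconds to a couple of minutes on a laptop
  core while keeping every statistical regime of interest — rank
  structure above the noise floor, p ≈ n classification, scarce
  positives — faithfully represented.

## Known limitations

Single run per participant; no stage-2 dual regression; no automatic
component-count estimation or noise-component classification; Gaussian
i.i.d. noise only; the within-participant protocol at the default
conservative effect size sits at chance (shown honestly in
`examples/04_within_participant.py`, together with a stronger
signature that is decodable) — real single-participant effect sizes
are unknown and not claimed.
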