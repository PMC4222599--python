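# intrumem

Decoding intrusive-memory formation from event-related fMRI.

After an analogue trauma — distressing film footage watched during
scanning — only some scenes later return as involuntary, image-based
intrusive memories, and which scenes intrude is idiosyncratic to each
viewer. `intrumem` implements, as a tested and reusable library, the
multivariate analysis that asks whether the brain activation recorded
*while a scene is viewed* predicts whether that scene will later
intrude: group spatial ICA feature construction over three
scene-relative time windows, cost-weighted linear classification of the
rare "flashback" class, and leakage-free leave-one-subject-out and
within-participant cross-validation. It is written for researchers in
experimental psychopathology and neuroimaging methods who want to
prototype, stress-test or teach this class of scarce-event decoding
pipeline.

Because no public dataset accompanies the original experiments, the
package ships a first-class synthetic-data module that generates whole
cohorts with the assumed statistical structure — 20 film scenes per
run, ~3 flashback scenes per participant (per-scene intrusion
probability 0.15, zero-intrusion participants resampled), TR = 3 s,
spatial networks whose flashback response is planted at known windows —
so every stage of the pipeline can be validated against ground truth.

## The method

Let `X_i ∈ R^{T×V}` be participant *i*'s preprocessed BOLD run (T
volumes, V voxels). The pipeline is:

1. **Group spatial ICA.** Runs are variance-normalized per participant
   and temporally concatenated to `X ∈ R^{ΣT×V}`; after rank reduction
   by SVD to k dimensions a fixed-point ICA unmixes `X ≈ A S` with
   independence over voxels, giving k unit-norm spatial maps
   `S ∈ R^{k×V}` (components are sign- and order-normalized; k = 39 by
   default).
2. **Dual regression (stage 1).** For each participant, every volume is
   regressed on all maps jointly: `tc_i = (S Sᵀ)⁻¹ S X_iᵀ`, a k × T
   activation time course per component.
3. **Window features.** For each scene, each component's time course is
   averaged over three half-open windows — `[onset, onset+6)`,
   `[onset+6, offset)`, `[offset, offset+12)` s, sampled at acquisition
   times `i·TR` — giving k × 3 features per scene (117 at k = 39).
4. **Cost-weighted linear classification.** Flashback scenes are
   outnumbered ≈5:1, so both families take a misclassification-cost
   multiplier `c ≥ 1` for the flashback class (default: the training
   potential:flashback ratio). LDA uses shrinkage-regularized pooled
   covariance with cost-adjusted priors; the SVM uses hinge loss with
   per-class costs. Features are z-scored with training-fold statistics.
5. **Evaluation.** Leave-one-subject-out: ICA, standardization and
   classifier are refit per fold on the training participants only, and
   the held-out participant's scenes are scored. Metrics are accuracy
   `(TP+TN)/N` and sensitivity `TP/(TP+FN)` — the fraction of the
   held-out participant's true flashback scenes identified. A
   permutation null (labels shuffled within training participants)
   calibrates the sensitivity. The within-participant variant selects
   the top-1000 voxels by two-sample t inside each
   leave-one-flashback-and-one-potential-out fold and classifies scene-
   averaged voxel features.

## Worked example

`examples/03_loso_decoding.py` runs the full pipeline on the canonical
desk-scale study — 35 participants, 39 networks of which 3 carry a
flashback effect of 2× the voxel noise SD, each in a single window:

```
study: 35 participants, 20 scenes, {'potential': 611, 'flashback': 89} scene labels

LOSO folds: 35 (one per left-out participant)
  fold  tp  fn  fp  tn  accuracy  sensitivity
sub-01   1   1   5  13      0.70     0.500000
sub-02   0   2   1  17      0.85     0.000000
sub-03   1   2   3  14      0.75     0.333333
sub-04   2   0   3  15      0.85     1.000000
sub-05   2   0   3  15      0.85     1.000000
...

mean accuracy    : 0.724 (SE 0.015)
mean sensitivity : 0.440 (SE 0.065)
```

Each row is one held-out participant: of sub-01's 2 flashback scenes
the classifier found 1, at the cost of 5 false alarms among the 18
potential scenes. Plain accuracy is dominated by the 5:1 imbalance
(always answering "potential" would score 0.85) — the reason
sensitivity is reported at all; the acceptance tests verify that on
this study the cross-validated mean sensitivity exceeds the 95th
percentile of a 100-shuffle permutation null. `examples/05_network_ranking.py` then shows that the top-ranked
classifier weights recover exactly the planted (network, window) pairs,
after matching ICA components to ground-truth maps.

The other examples cover study simulation and file formats (`01`),
group ICA recovery of planted networks (`02`), and within-participant
decoding (`04`).

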