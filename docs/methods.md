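# Methods

## Model and procedure

The package treats drug–target interaction (DTI) prediction as a
positive–unlabeled (PU) binary classification problem over drug–target pairs.
A pair is represented, per *feature pair* `i`, by the concatenation of a drug
descriptor vector and a target descriptor vector; three feature pairs are used
by default (fingerprint-type drug blocks of 79/166/307 columns against
composition-type target blocks of 20/80/160 columns).

One experiment repeat consists of:

1. **Cold-start split.** Entities on the split axis (drugs by default) are
   randomly assigned to train/validation/test at 0.6/0.2/0.2; validation and
   test sizes are floored and the remainder goes to train (so 54 drugs split
   34/10/10). Every pair inherits its entity's role; the three role sets are
   disjoint by construction, which is asserted in tests.
2. **Training negatives (per feature pair).** Within the training partition,
   pair vectors are min–max normalized, projected by PCA (smallest component
   count reaching 95 % explained variance), and each unlabeled pair is ranked
   by Euclidean distance from the centroid of the training positives.
   The top `n` pairs (default `n` = number of training positives, i.e. a
   balanced training set) become that feature pair's negatives. Each sub-model
   gets its *own* negatives; only evaluation partitions use union pools.
3. **Sub-models.** One soft-margin RBF-kernel SVM per feature pair
   (`C = 2⁻⁴`, `γ = 2⁻⁷`, libsvm backend through scikit-learn), trained on the
   partition-fit min–max normalized pair vectors (no PCA; see "Feature spaces"
   below). Raw signed decision values are used downstream, uncalibrated.
4. **Evaluation sets.** Within the validation (resp. test) partition the same
   normalize→PCA→rank procedure runs per feature pair, using that partition's
   own positives as the centroid population; the three selections are merged
   into the union pool `U-vali` (resp. `U-test`) and a balanced negative
   sample is drawn uniformly, reproducibly by seed.
5. **Weight optimization.** The ensemble score is `dec = Σ w_i·dec_i`. All
   weight vectors on the probability simplex with step 0.1 (66 points,
   including the three corners) are evaluated by validation AUC; ties keep the
   first point in (w1 ascending, then w2) order. The winning vector is frozen
   and applied to the test partition. AUC uses a threshold sweep with tied
   scores collapsed (trapezoidal area = tie-adjusted Mann–Whitney
   `U/(n₊n₋)`); threshold metrics (accuracy, precision, recall, F1) are
   computed at `dec > 0`, with 0/0 reported as undefined rather than 0.

Repeats derive their split seed as `base_seed + k`, so paired comparisons
(random-vs-distance sampling, intact-vs-degraded features) share splits.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| ratios | 0.6/0.2/0.2 | entity-level train/validation/test fractions |
| train_negative_ratio | 1.0 | negatives per training positive (balanced) |
| variance_target | 0.95 | PCA retained variance before distance ranking |
| c, gamma | 2⁻⁴, 2⁻⁷ | SVM cost and RBF width, fixed across feature pairs |
| weight_step | 0.1 | simplex grid resolution (66 candidates) |
| threshold | 0.0 | decision threshold for confusion-based metrics |
| normalization | minmax | fingerprint bits/counts and composition fractions have bounded, unit-heterogeneous ranges; z-score available |

The number of training negatives and the balanced validation/test draws are
deliberate choices: balanced evaluation sets keep AUC comparable across
repeats and datasets.

## Feature spaces (design decision)

Normalization and PCA are motivated by the Euclidean distance computation, so
they are applied exactly there: rankings run in the per-partition
normalized+projected space, and the positive centroid is computed in that same
space. The SVMs, by contrast, are trained on min–max normalized (not
PCA-projected) vectors using the *training*-partition normalizer, which is
then reused to transform validation/test vectors — standard supervised
practice that keeps the classifier's input space consistent across partitions.
Evaluation-partition rankings use each partition's own positives as the
centroid population, matching the pool-construction flow in which distances
are computed inside each set.

Decision values are fused without calibration. This is the largest
interpretive risk in the design: sub-model decision-value scales differ, so a
weight partly compensates scale rather than pure importance. A per-model
standardization option exists in principle behind the weight-grid interface
(divide scores by their training sd before fusing) but is off by default
because raw-value fusion is the stated formula.

## Synthetic benchmark

The generator emulates the input bundle of a chemogenomic gold-standard
benchmark: a binary interaction matrix (default 54 drugs × 26 targets with 90
interactions, the nuclear-receptor-like shape — chosen as the default profile
because it is the smallest realistic benchmark shape and keeps 20-repeat
experiments fast) plus three drug and three target descriptor tables.

Entities are *core* or *outlier* (default 15 % of each axis). Core entities
cluster around a shared per-feature-pair base profile; positives are placed
uniformly on core×core cells. Outlier entities carry an additional offset, and
the **planted reliable negatives** are the outlier-drug × outlier-target
pairs. All other unlabeled pairs are ambiguous: core×core pairs are
statistically indistinguishable from positives (the PU premise), mixed pairs
lie between the clouds.

Column types mirror real descriptor families so min–max normalization is
exercised non-trivially: two drug blocks are 0/1 fingerprints (base pattern
with 2 % flip noise), one holds small substructure counts (±1 jitter), and
target blocks are simplex-normalized compositions (base composition mixed with
flat-Dirichlet noise).

**Separation calibration.** `separation` is the distance of the planted
cloud from the positive centroid in multiples of the core cloud's RMS radius
(the "noise scale"), *measured in the min–max normalized space where distances
are actually computed*. Because min–max rescales each column independently, a
column's offset-to-noise ratio survives normalization but cross-column
weighting does not; offsets are therefore laid out proportionally to each
column's noise scale (binary: `m` flipped columns with
`m = ⌈sep²·D·ε(1−ε)/(1−2ε)²⌉`; counts: `m` columns shifted by +3 with the
analogous normalized-range formula; compositions: an equal-magnitude,
zero-sum per-column shift of the base composition with the Dirichlet noise
weight shrinking as 1/sep so rows stay on the simplex). At a per-coordinate
reading of "noise scale" the planted points would sit *inside* the core cloud
at realistic dimensionalities (the cloud radius grows as √dim), so the radius
reading is the one under which planted-negative recovery is well-defined.

Each feature pair draws its own base patterns, noise and offset columns:
the three views share the same truth but not the same geometry, so ensemble
fusion has something to gain.

`degrade_feature_pair` convexly mixes one feature pair's tables with
column-shuffled noise; at `signal_fraction = 0` every entity-level association
in that view is destroyed while column marginals are preserved.

**What the generator does not emulate:** real chemistry — descriptor
correlations within a block, fingerprint bit co-occurrence structure,
target-family clustering, and the extreme positive sparsity of the large
benchmarks (the default profile is ~6 % positive, like the smallest real
benchmark but unlike the ~1 % of the largest). Passing tests therefore
demonstrate that the machinery is correct and that the method recovers
*geometrically* reliable negatives; they do not certify AUC levels on real
descriptor tables.

## Degradation ablation (frozen samples)

Comparisons between arms (ensemble vs individual sub-models; intact vs
degraded features) hold **all positive and negative samples identical across
arms**: selections, pools and evaluation draws are computed once from the
reference data and re-used (`pipeline.run_paired_arms` / `SamplePlan`). This
matters because the union pool lets even a pure-noise feature pair seed the
evaluation sets with its own far-in-noise-space selections, which that
sub-model then recognizes at test time — re-sampling from degraded features
measures this pool-contamination effect (degraded sub-model AUC ≈ 0.67 rather
than 0.5) instead of the feature ablation. With samples frozen, a degraded
feature pair's optimized weight collapses in every repeat.

## Numerical choices

- Distance ties break by ascending (drug_id, target_id); weight-grid ties by
  enumeration order (w1 ascending, then w2); both make runs deterministic.
- PCA components fix their sign so the largest-magnitude loading is positive;
  constant columns min–max-map to 0 without division by zero; out-of-range
  values in new data are extrapolated, never clipped.
- Union-pool membership is sorted lexicographically before seeded draws, so
  samples depend only on the seed, not insertion order.
- A repeat whose validation or test partition has no positives aborts with a
  recorded reason and is excluded from summaries (possible only for very small
  or very sparse matrices).

## Problem sizes

Tests and the acceptance script run the default 54×26 profile (1,404 pairs,
full descriptor dimensionalities, 20 repeats per experiment) and a tiny
12×8 profile with 8/4-dimensional descriptors for unit tests. These sizes
exercise every stage of the method at full descriptor dimensionality while
keeping a complete run in seconds on one CPU core; dense storage and
brute-force grid search are appropriate at gold-standard benchmark scale
(≤ 445×664 pairs per axis, 66 grid points).

## Known limitations

- Uncalibrated decision-value fusion entangles weight magnitude with score
  scale (see above).
- The weight grid is exhaustive only for three sub-models at coarse steps;
  more feature pairs would need a smarter search.
- AUC on balanced drawn negatives is an optimistic proxy for ranking the full
  unlabeled universe; no attempt is made to score all unlabeled pairs.
- Entity-wise splitting controls leakage on one axis only; a by-drug split
  still shares targets between train and test, so target-side memorization is
  possible (and observable in ablations).
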