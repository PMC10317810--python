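# Methods

## The prediction problem

A two-arm randomized trial (quetiapine vs. lithium) in youth with bipolar
I disorder measures mania severity with the Young Mania Rating Scale
(YMRS; inclusion requires baseline ≥ 20). A subject is a *responder* when
the week-6 YMRS shows a reduction of at least 50% from baseline; the
boundary is inclusive and the reduction is computed in floating
arithmetic with no rounding before the comparison. The pipeline predicts
this binary outcome from regional brain morphometry measured at baseline
and after one week of treatment.

## Feature schema

Each subject is a 150-vector: thickness and surface area of the 68
Desikan–Killiany cortical regions (34 per hemisphere) and volumes of 14
subcortical structures (bilateral hippocampus, thalamus, amygdala,
caudate, putamen, pallidum, accumbens). The within-vector order — all
thickness, then all area, then volumes; left before right; aparc
alphabetical region order — is a repository convention; nothing
downstream depends on it beyond reproducibility. Three feature sets are
built from the two scans: baseline (150), 1-week change defined as
baseline − week 1 (150; positive = decrease), and the longitudinally
joint concatenation (300, `baseline_*` then `week1_*`). Tables align
subjects by id, never by row order; missing values are rejected rather
than imputed (the analysis is complete-case; `drop_incomplete_subjects`
is the explicit cleaning utility).

## Two-stage model

**Stage 1 (non-linear dimensionality reduction).** Raw features are
binarized per feature. The default is a median split fitted on training
rows with strict `>` (ties map to 0): rank-based and therefore scale-free
across measures spanning three orders of magnitude (mm / mm² / mm³). A
min–max squashing to [0, 1] with out-of-range clipping is available where
a continuous unit-interval input is preferred. A stack of sigmoid layers
(default widths 64 → 32 → 8 from 150 inputs) is pre-trained greedily:
each layer's autoencoder reconstructs the previous layer's activations
under cross-entropy, matching the binary/unit-interval inputs. The stack
plus a 2-unit softmax head is then fine-tuned on the responder labels.
The last hidden layer's activations are the subject representation.

**Stage 2.** An SVM (default: linear kernel, C = 1, balanced class
weights) is fitted on the training representations. Decision scores are
always computed from the stored arrays rather than by re-entering the
SVM library, so serialized models reproduce predictions bitwise.

**Training schedule.** Plain minibatch SGD, batch 16, fan-based uniform
(Glorot-style) initialization drawn from the run seed. The default
learning rate is 0.1 with 100 pre-training and 200 fine-tuning epochs:
at rate 0.01 the sigmoid stack under-trains badly on n ≈ 100 cohorts
(representations collapse and held-out BAC sits at chance on signals a
plain SVM separates), while 0.1 recovers planted signals cleanly. No
inner hyperparameter search is performed — the evaluation protocol
contains none — but every knob is exposed in `TwoStageConfig`.
`layer_sizes=()` disables the encoder, reducing the pipeline to an SVM on
squashed features; this degenerate configuration is the regression oracle
used in tests. All hidden widths must be smaller than the input dimension
(compression contract) and the final width stays well below the per-arm
sample size to limit SVM overfitting.

**Determinism and leakage.** The whole fit is a pure function of
(training data, config, seed); binarizer thresholds, weights and SVM
state depend on training rows only. Tests assert byte-identical
serialized models across refits and across held-out-row perturbations.

## Evaluation protocol

Stratified 10-fold cross-validation; per fold the entire pipeline is
refitted on the nine training folds. Headline metrics are computed on
the pooled held-out predictions across folds (per-fold metrics are also
reported); pooling was chosen because a single metric per model is
reported and pooled counts keep the BAC identity
BAC = (sensitivity + specificity)/2 exact. Sensitivity is the
true-positive rate on responders; AUC is the pairwise win probability of
decision scores with ties counted half (verified against a brute-force
pairwise oracle). Significance: the full label vector is permuted once
per repetition (preserving class balance — the standard exchangeable
null), the identical cross-validation is rerun, and
p = (1 + #{null BAC ≥ observed}) / (n_perm + 1) (add-one form, so p is
never 0 and the test is finite-sample valid). Transferability fits the
pipeline on one entire arm and evaluates on the other. Contributions are
ranked either by connection weights (row sums of |W₁|·…·|W_L|, a
property of the encoder, invariant to common positive rescaling) or by
permutation importance (mean held-out BAC drop over repeated shuffles of
one raw feature column, negatives clipped); scores are normalized to the
unit simplex, and in the cross-validation context are averaged over
fold-models before ranking (each fold-model's permutation importance is
probed on its own held-out fold). Ties in top-k break by canonical
feature order.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth. Per analyzed subject with latent status
s = ±½ (responder = +½) and feature j with per-measure scale (μ_j, σ_j):

    baseline_j ~ N(μ_j + s·d_j·σ_j, σ_j²)
    week1_j    = μ_j + ρ(baseline_j − μ_j) − s·δ_j·σ_j + ε_j,
                 ε_j ~ N(0, τ²σ_j²)

d_j is nonzero only on that arm's baseline effect features and δ_j only
on its change effect features. Defaults and why:

* **Scale profile** thickness 2.5 ± 0.15 mm, area 2500 ± 400 mm²,
  volume 4000 ± 600 mm³ — physiologically plausible magnitudes so the
  scale-free binarization is genuinely exercised across three orders of
  magnitude; conventions, not claims.
* **ρ = 0.5** baseline–week-1 correlation. One-week stability in an
  acutely manic pediatric sample under active dose titration combines
  trait stability with genuine drug-induced change and scan noise, so a
  moderate value is assumed rather than the excellent test-retest of
  stable adults. ρ also governs the difference-vs-concatenation
  trade-off discussed below. τ defaults to √(1−ρ²), which makes the
  week-1 marginal variance equal the baseline variance and the empirical
  correlation converge to ρ (verified at n = 2000 within ±0.05).
* **YMRS trajectories.** Baseline ~ integer uniform on [20, 40];
  responder week-6 reductions ~ U(0.60, 0.95), non-responders
  ~ U(0.05, 0.40). Integer rounding of week-6 scores can move a
  reduction by at most 0.5/baseline, and the spec validator requires the
  ranges to clear 50% by that margin, so the ≥50% rule recovers the
  latent status with probability 1 by construction.
* **Default effect patterns** are disjoint between arms
  (temporal/subcortical features for the quetiapine-like arm,
  frontal/parietal for the lithium-like arm), mirroring the qualitative
  finding that predictors differ by drug; this is what the
  transferability suite exploits.
* **Flow preset**: 149 recruited, 9 excluded at baseline MRI, 79/61
  randomized, 8/11 lost → 71/50 analyzed.

What the generator does **not** emulate: spatial covariance between
neighboring regions, site/scanner effects, non-Gaussian morphometry, or
any relation between covariates (age, sex) and outcome. Passing tests
therefore demonstrate that the pipeline recovers mean-shift signals of
the stated sizes under independent Gaussian noise — not performance on
real morphometry.

## Simulation study conditions and problem sizes

Simulation suites use reduced training schedules (`morphpred.presets`):
`fast_config` (32→16→8, 30/100 epochs, rate 0.3) for cross-validation
studies and `tiny_config` (16→4, 5/20 epochs, batch 32) for
permutation-calibration sweeps where hundreds of refits are needed. The
pipeline structure is identical to the default schedule throughout.

* Null calibration: 20 cohorts (n = 120, no signal), 10-fold CV; and 50
  cohorts (n = 60) × 60 permutations at k = 5 for type-I error of the
  permutation test at α = 0.05.
* Signal recovery: d = 1.5 on 10 features, n = 120 — pooled CV BAC
  ≥ 0.75 and permutation p ≤ 0.01 at 200 permutations.
* Transferability: two arms of 60 with disjoint d = 1.5 patterns
  (within-arm CV BAC ≥ 0.75; cross-arm BAC averaged over 5 replicate
  cohorts ≈ 0.5, single-draw sd ≈ 0.07) and a shared-pattern positive
  control (cross-arm BAC ≥ 0.70).
* Contributions: 10 cohorts as in signal recovery (≥ 6/10 planted
  features in the top 10, median); single-feature cohorts at d = 2.0 for
  rank-1 agreement of both ranking methods.

## The joint-model comparison: a known limitation

The study design predicts that the joint (baseline + week 1) model
performs best. Under this generator that holds **in expectation** —
with equal-strength complementary signals (d = 1.0 baseline-only on ten
features, δ = 1.0 change-only on ten others, n = 120) the joint model
has the highest mean CV BAC (≈ 0.84 vs ≈ 0.81 change / ≈ 0.77 baseline
over ten seeds) — but its per-seed dominance over the change model is
only ≈ 60–70%, short of a strict ≥ 70% bar. The reason is structural: a
week-1 mean shift δ appears in the change table at effective size
δ/√(2(1−ρ)) but in the raw week-1 columns at δ, so for ρ ≥ 0.5
differencing never loses; binarizing the raw baseline and week-1 columns
prevents the joint model from reconstructing differences, and the joint
model also pays a doubled noise-dimension cost. The corresponding
acceptance test asserts the strict per-seed bar and is expected to fail
under these conditions; it is kept as an honest record of the
limitation rather than weakened.

## Numerical choices

* Median-split ties map to 0 (strict `>`); constant training features
  warn and map to all-zeros (median) or 0 (min–max).
* Cross-entropy probabilities are clipped at 1e-12; non-finite epoch
  losses raise a divergence error naming layer and epoch.
* Per-fold model seeds derive deterministically from the evaluation
  seed; fold seed and model seed are independent and both recorded.
* Contribution scores that are identically zero after clipping fall back
  to the uniform distribution (no information ≠ missing output).
* Feature tables round-trip bit-exactly: values are written with
  Python's shortest-repr and parsed with numpy's correctly-rounded
  string conversion (pandas' fast parser can be one ulp off).
* Model archives are npz files holding a JSON header plus named float64
  arrays; round trips preserve predictions bitwise.
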