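# Methods

## Pipeline

Each subject is a T×m matrix of region-averaged signals. The pipeline per
cross-validation fold is:

1. **Connectivity.** Pearson correlation between every region pair;
   strictly-upper-triangle vectorization in row-major pair order
   (q = m(m−1)/2 values). A zero-variance region yields correlation 0 with
   every other region (logged), not an error: a neutral value that cannot
   enter either extreme of the mask, so degenerate synthetic inputs do not
   abort a fold.
2. **Masking.** The training-fold connectivity vectors are averaged
   element-wise; the indices of the ⌊q/4⌋ largest and ⌊q/4⌋ smallest
   averaged values form the feature mask applied to both training and test
   subjects. The kept fraction is configurable
   (`FeatureConfig.keep_fraction`, default 0.25 per extreme); there is no
   intrinsic limit on how many high/anti-correlations to keep, but keeping
   half is the default trade-off between overfitting and losing pattern.
   Ties break toward the lower index, and the two arms are kept disjoint
   even under massive ties, so |mask| = 2·⌊q/4⌋ always and the mask is
   platform-deterministic.
3. **Augmentation.** See below.
4. **Model.** Tied-weight autoencoder + single-layer perceptron trained
   jointly, then SLP-only fine-tuning.
5. **Scoring.** Held-out subjects are masked with the training-fold mask and
   scored by the trained model; accuracy, sensitivity, specificity and
   trapezoidal ROC AUC are computed per fold and averaged.

## EROS similarity and augmentation

EROS compares two multivariate time series through the eigenstructure of
their sample covariances (column-centered, T−1 divisor):
EROS(A,B,w) = Σᵢ wᵢ|⟨aᵢ,bᵢ⟩| over rank-paired unit eigenvectors. Properties
relied on (and tested): symmetry, range [0,1], invariance to eigenvector
sign. Only the n = 2 leading components are kept by default — a speed
simplification that leaves neighbour rankings essentially unchanged — and
each subject's eigen summary is computed once and reused.

The weight vector comes from the eigenvalue matrix S (n × N, one column per
training subject): columns normalized to sum 1, rows aggregated (mean by
default), result renormalized to sum 1. When n < m the per-item
normalization divides by the sum of the *retained* eigenvalues, which keeps
Σwᵢ = 1 exact; the weights are computed from the training fold only
(whole-dataset weighting would leak test eigenvalues into training).

Augmentation is SMOTE-like in masked-feature space: for each training
sample, one of its k = 5 nearest same-class neighbours (by EROS) is drawn
uniformly and a convex combination α·p + (1−α)·q, α ~ U[0,1], is added with
the seed sample's label. One synthetic sample per real sample doubles the
training set. Synthetic samples take part in both loss terms. The synthetic
label is unambiguous because both parents share a class; a sample with no
eligible neighbour (a lone class member in a fold) is skipped with a
warning. Provenance (seed index, neighbour index, α) is recorded for audit
and the whole procedure is bit-reproducible from its seed.

## Model and training

Encoder h = tanh(W_enc x + b_enc); decoder x′ = W_encᵀ h + b_dec. The
decoder weight is never materialized — decoding reads the current encoder
weight — so the tied-weight constraint cannot be violated at any point in
training. Classifier f(x) = σ(W_slp h + b_slp); ŷ = 1 iff f(x) ≥ 0.5 (the
boundary maps to the patient class).

Loss: MSE(x, x′) + BCE(y, f(x)) with unit weights (configurable).
Cross-entropy uses logarithms with probabilities clipped to
[1e−7, 1 − 1e−7]; a printed form of the loss without logs is not a proper
scoring rule, so standard BCE is implemented. Joint training runs 25 epochs
of Adam (lr 1e−3); fine-tuning runs 5 more epochs on the cross-entropy only
with the encoder frozen (a flag allows joint fine-tuning for sensitivity
analysis).

The network is implemented in numpy with analytic gradients and a minimal
Adam, which keeps the package dependency-light; gradients are checked
against central finite differences (rtol 1e−5) in the test suite. Weights
initialize uniform ±1/√fan_in, biases zero, seeded.

**Batch size.** Default 8. With near-zero initialization, full-batch Adam
at lr 1e−3 for 25 epochs bounds the total parameter displacement by
≈ epochs × lr and cannot reach a useful solution at desk scale; minibatches
of 8 give a few hundred updates on a ~100-subject fold, which converges
reliably on separable data while remaining deterministic from the seed.
`batch_size=None` selects full batch for users who want it. Batch size,
weight decay and early stopping are this package's own defaults, not values
inherited from any reference cohort study.

**Bottleneck.** Default ⌊input_dim/2⌋, continuing the halving pattern of
the feature pipeline (q → q/2 by masking → q/4 in the bottleneck);
configurable.

## Evaluation harness

Stratified k-fold (class-label stratification; without it, small sites
produce single-class test folds). Pooled analyses default to k = 10,
per-site analyses to k = 5 — large pools afford more training data per
fold, while a 5-fold split keeps per-site test sets from shrinking to 2–3
subjects. Fold assignment is seeded; per-fold provenance hashes (training
ids + mask indices) make leakage audits and exact reruns possible.
Site-aware stratification of pooled CV is available by flag, off by
default. Rates with empty denominators (e.g. sensitivity in an all-control
fold) are NaN, an explicit undefined marker, and mean rows average with
NaN-awareness. ROC/AUC use the trapezoidal rule over all thresholds, which
equals tie-aware pairwise concordance; fold metrics with a single-class
test fold get NaN AUC.

## Synthetic data

The generator emulates the one statistical property the classifier
consumes: class-dependent covariance between regions. Class 0 draws
zero-mean Gaussian series with unit variances and uniform off-diagonal
0.1; class 1 shifts the covariance at 12 known region pairs by ±0.6 (signs
alternating so both mask arms are exercised). Defaults: m = 20 regions,
T = 150 timepoints, 50 subjects per class. Default pairs are vertex-disjoint
where possible and otherwise spread out, which keeps the perturbed matrix
nearly positive definite; any remaining deficit is repaired by a small
ridge (≈ 0.07 at the defaults, logged), and a delta so large that the ridge
would exceed 0.5 aborts with advice. Series are temporally white by default
(Pearson correlation and covariance eigenstructure are then exactly
controlled); an optional AR(1) coefficient adds temporal smoothness with
innovation scaling that preserves the stationary covariance, and an
optional per-site mean shift introduces site heterogeneity for the
site-wise harness.

What passing tests show: the pipeline recovers planted covariance structure
and returns to chance when it is absent. What they do not show: performance
on real fMRI, where autocorrelation, site effects, motion artifacts and
much weaker, distributed class differences apply — real cohorts of this
kind typically yield around 0.6–0.7 accuracy, not the 1.0 of the clean
synthetic conditions.

## Problem sizes and numerical choices

Tests and the acceptance script run the default synthetic conditions
(100 subjects × 20 regions × 150 timepoints, 5-fold CV, 5 generator seeds
for the separable case and 5–10 for the null), chosen as the smallest
configuration that exercises every pipeline stage with stable statistics.
Tolerances: exact-arithmetic checks at 1e−12 (Pearson and EROS against
brute-force oracles), gradient checks at 1e−5 relative, weight-sum and
convexity invariants at 1e−12–1e−15. Eigen-decomposition uses `eigh`
(symmetric), with descending sort and sign canonicalization (largest-
magnitude entry positive) for cross-platform determinism.

## Known limitations

- The model is a shallow 1-hidden-layer network; it is a strong baseline,
  not a state-of-the-art deep architecture.
- EROS rank-pairing of eigenvectors is unstable when eigenvalues are nearly
  degenerate; with n = 2 this matters only for nearly isotropic subjects.
- Augmentation interpolates in masked-feature space; it never generates raw
  time series.
- The NaN-marker convention for undefined rates propagates into mean rows
  only through NaN-aware averaging; downstream consumers must not treat NaN
  as zero.
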