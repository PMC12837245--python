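# Methods

## Overview

`bcghyper` classifies 5-minute ballistocardiograph (BCG) segments as normal
or hypertensive through a three-stage pipeline — feature extraction, wrapper
feature selection, boosted classification — scored by subject-level
stratified k-fold cross-validation. This note records the models, the
defaults and why, what the synthetic data does and does not emulate, and the
design choices made where the design was genuinely open.

## Synthetic cohort generator

Each subject is rendered as a pulse train plus baseline plus noise:

* a per-subject heart rate drawn from the group distribution
  (hypertensive 77.1 ± 9.2 bpm, control 73.6 ± 8.3 bpm — the published
  cohort statistics), clipped to [30, 180];
* beats placed by an inter-beat-interval process `IBI = 60/HR · (1 + 0.03 ε)`
  with standard-normal ε — the 3% per-beat jitter keeps interval features
  non-degenerate;
* each beat a Gaussian-windowed sinusoid (~3 visible oscillations over
  0.25 s), standing in for the I-J-K complex. Hypertensive beats are scaled
  by `pulse_amp_ratio` (default 1.3) in amplitude and `1/sqrt(ratio)` in
  width — stiffer vasculature producing stronger, sharper recoil. At
  ratio = 1 with equal heart-rate parameters and zero noise the two class
  processes are identical, so the label carries no information (a tested
  degenerate contract);
* a sinusoidal respiratory baseline at 0.25 Hz, amplitude 0.3 (beat
  amplitude is 1.0), random phase;
* additive white Gaussian sensor noise, SD 0.1.

Defaults: 100 Hz, 300 s records, 40 + 40 subjects. These were fixed as the
study conditions before any evaluation and are not tuned.

**What passing tests show — and don't.** The generator produces a separable
but noisy two-class problem with realistic rates and timing; it does *not*
model motion artifacts, posture changes, inter-subject morphology diversity,
BMI/blood-pressure covariates, or nonstationary noise. High accuracy here
demonstrates that the pipeline machinery is correct and leak-free, not that
the method reaches any particular accuracy on clinical recordings.

The labeled Gaussian table generator (`generate_feature_table`) provides
ground truth for selection and classification: informative columns carry a
class-mean shift equal to `effect_size`; noise columns are class-independent
standard normal; column names mark which is which.

## Preprocessing

* **ICA cleaning** (dual-channel records): FastICA unmixing, components with
  excess kurtosis > 10 zeroed, re-projection. Heartbeat trains are far less
  leptokurtic than spike artifacts, which motivates the kurtosis heuristic;
  the threshold is a placeholder in the absence of a published rule.
  Single-channel records pass through with a warning.
* **Segmentation**: non-overlapping windows (default 300 s), trailing
  partial window dropped. Non-overlap avoids inter-fold duplication of
  samples.
* **Standardization**: per-column z-score with statistics from training rows
  only; constant columns map to zero with a warning.

## Feature extraction

* **K-means** (K = 4, 2-s frames): frames summarized by (mean, SD, energy,
  peak-to-peak), clustered by Lloyd's algorithm with squared-Euclidean
  dissimilarity; features are the centers (sorted by their energy coordinate
  for determinism), occupancy fractions and inertia — 21 features.
* **MODWT** (db4, 5 levels): undecimated transform via `pywt.swt` with
  `norm=True` (energy-preserving; every band has the input's length).
  Inputs not divisible by 2^levels are symmetrically padded and coefficients
  trimmed, so the exact energy/reconstruction identities hold on unpadded
  lengths. Per band: mean |·|, variance, energy fraction, skewness,
  kurtosis — 30 features.
* **EWT** (5 modes): boundaries at midpoints between the largest spectral
  maxima; Meyer-polynomial crossfades form a partition of unity over the
  spectrum, so the modes sum back to the signal to machine precision.
  Spectra with fewer maxima fall back to fewer modes (zero-filled feature
  slots keep the table width fixed). Per mode: energy fraction, spectral
  centroid, variance, Hjorth mobility — 20 features.
* **PCA / kernel PCA** (default linear kernel, 4 components, per the
  published operating point; the Gaussian and polynomial kernels are
  exposed): fitted on a 23-dimensional raw descriptor table (time-domain
  moments and quantiles, Hjorth parameters, fixed spectral-band energy
  fractions, spectral centroid, an FFT-autocorrelation inter-beat-interval
  estimate). Where the source material names both a Gaussian and a linear
  kernel, the linear operating point is the default.
* **RFM** (10 groups × 8 ReLU nodes, lasso penalty γ = 0.01): random linear
  maps fine-tuned by a sparse autoencoding lasso from the inputs onto the
  random pre-activations (γ = 0 reduces to least squares; large γ drives
  the weights to zero).

The scalar feature sets taken from the decompositions are this package's
definition (recorded in each table's provenance); sizes were chosen so the
total dimensionality stays well below the sample count.

## Feature selection

Wrapper fitness: `0.99·error + 0.01·FSR`. The error term is a 3-fold
stratified internal CV of a 10-NN classifier on the masked training table —
10-NN because the evaluation stage fixes k = 10, 3 folds as the cheapest
stable estimate. The 10-NN scorer is a vectorized distance-matrix
implementation with per-mask caching (the metaheuristics evaluate thousands
of masks); ties vote for the lower class.

* **BTSA**: jet-propulsion dynamics with force `T = G/S`,
  `G = k1 + k2 − 2k3`, social force `S = w_min + k3 (w_max − w_min)` with
  speeds 1–20, move toward/away from the best tunicate on a coin flip, then
  the averaging update `(B + B_best)/(2 + k1)` — implemented as printed,
  including the typographically ambiguous denominator.
* **AOA**: four hunting strategies — high soar around the population mean
  and Levy-flight contour spiral in the first ⅔ of iterations, low-flight
  descent (λ = σ = 0.5) and quality-factor dive afterwards, chosen with
  probability ½ within each phase. Levy scale
  `σ = Γ(1+α)·sin(πα/2) / (Γ((1+α)/2)·α·2^((α−1)/2))` with α = 0.5 and
  step constant c = 0.1. The undefined spiral constant U uses the
  literature convention 0.00565, the dive coefficients are
  `G1 = 2·rand − 1`, `G2 = 2(1 − t/T)`.
* **Binarization** (both, and binary PSO): a bit is complemented when a
  uniform draw falls below the V-shaped transfer of the continuous update,
  else retained; empty masks are repaired by activating one random bit.
  All wrappers are elitist — the best mask ever evaluated is returned, so
  best-fitness traces are non-increasing — and bit-reproducible per seed.
* **Filters**: information gain (equal-frequency bins, base-2 entropies,
  keep above-mean scorers), chi-square on binned contingencies,
  point-biserial correlation; binary PSO and binary ACO share the wrapper
  fitness.

## Classifiers

* **MULDA**: within-class scatter `M_q = M_w/(n−c)` eigendecomposed;
  eigenvalues below their mean raised to the mean — the reading in which
  larger eigenvalues do not change, preferred over wholesale replacement
  because replacement would destroy all discriminative scaling of the
  within-class spectrum. Discriminants are the leading c−1 eigenvectors of
  `(M_w*)^−1 M_b`; classification by 10-NN in the projected space. With a
  spherical within-class spectrum the procedure reduces exactly to LDA
  (tested to 1e-8).
* **Boosting core**: weighted training is realized by weight-proportional
  resampling of size n; an exactly uniform weight vector uses the full
  sample unchanged, which makes every single-round ensemble identical to
  its plain base learner (a tested reduction identity). Voting weight
  `α = ½·log((1−ε)/ε)` with ε clipped to [1e-10, 0.5−1e-10]; early stop on
  ε = 0 or ε ≥ 0.5. Sample weights renormalize to 1 every round and the
  classical training-error bound `Π_t 2√(ε_t(1−ε_t))` is asserted on every
  tested run.
* **ARIMA–AdaBoost**: stage 1 augments each segment's selected features
  with its ARIMA(2,1,2) summary (AR/MA coefficients, residual variance,
  mean). Orders are configurable; (2,1,2) is a compact default.
  Stationarity is screened by an augmented Dickey-Fuller test (differencing
  drops to 0 when the unit-root null is rejected); fits use the fast
  Hannan-Rissanen estimator on segments decimated to 10 Hz — coefficient
  features need only the coarse dynamics — with a pure-AR fallback on
  non-convergence. Note that full ARMA(2,2) on white noise is unidentified
  (near-canceling roots); the white-noise recovery tests therefore use AR
  orders, matching their sampling-distribution oracle. Stage 2 is an
  AdaBoost.R2-style booster of depth-1 regression trees on 0/1 targets with
  `β_t = ε_t/(1−ε_t)`, distribution update `D ∝ D·β^(1−e_i)` and the
  weighted-mean score thresholded at 0.5.
* **TW-HASVM**: polynomial-kernel SVMs (degree 3, C = 1 — unspecified
  upstream, standard defaults) boosted with initial weights scaled by
  `TW(t) = exp(−ηt)` (t = batch age; a per-sample vector is accepted) and
  the one-sided update `w ← w·exp(α·1[miss])`. With a single batch the time
  weight is a scalar that renormalizes away, so any η gives identical
  models; this reduction — and equality with an independently coded plain
  boosted-SVM pipeline — is tested at the prediction level. The one-sided
  update differs from the two-sided `e^{∓α}` of the classical discrete
  AdaBoost by a factor of `e^{α}` in the miss/correct ratio; both families
  are implemented as specified by their respective procedures.
* Prediction: per-class weighted vote `S_cl = Σ α_t·1[h_t = cl]`, argmax,
  ties to the lower class index. The machinery is generic in the number of
  classes but tested for the binary task.

## Evaluation

Folds are stratified over subjects; every segment inherits its subject's
fold, preventing identity leakage (the unit of classification is the
segment — with 300-s windows on 300-s records, one per subject). The
permuted-label null is the leakage canary: any train/test contamination
would lift it above 50%. Confusion matrices are persisted per fold so
sensitivity/specificity can be derived later. The statistics battery
(per-feature Kruskal-Wallis and two-sided Wilcoxon rank-sum, Friedman
across columns, Cohen's kappa of a CV'd 10-NN reference) is descriptive
only and never filters features; p-values are reported uncorrected, with a
Benjamini-Hochberg option off by default, matching descriptive use.

## Numerical choices

* Error/eigenvalue clips: boosting errors to [1e-10, 0.5−1e-10]; kernel
  eigenvalues must be ≥ −1e-8 relative (else a PSD error).
* K-means centers ordered by energy coordinate; KNN and argmax ties to the
  lower class; Levy denominators floored at 1e-12.
* EWT transition half-width γ·b with γ the tightest-gap ratio capped at
  0.45 and floored at 1e-6.
* All stochastic stages consume a `numpy.random.default_rng` seeded from
  their arguments; identical seeds give bit-identical results.

## Problem sizes used in tests and the acceptance run

Deliberately desk-scale, chosen once: wrapper searches at pop ≤ 20 and
≤ 50 generations (the published operating point of 100 agents × 1000
generations remains the `full` profile default), boosting at T ≤ 20, the
default 40 + 40-subject cohort, 10 permutation seeds for the null. These
sizes are the package's own smoke-scale conditions; the `full` profile
exposes the published ones.

## Known limitations

* The synthetic class contrast is a stand-in; no claim is made that its
  amplitude/width mechanism reflects hypertensive BCG physiology.
* Published real-data accuracies are not reproducible from this package
  alone: they depend on an external dataset and preprocessing details
  (segment vs subject CV units, ICA configuration, fitness internals) that
  are not fully specified anywhere.
* ARMA orders with redundant roots are unidentified; coefficient features
  from such fits are stable only because the estimator and decimation are
  fixed.
* TW-HASVM's multi-batch weighting is implemented but exercised only with
  synthetic batch indices; no streaming-data evaluation exists here.
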