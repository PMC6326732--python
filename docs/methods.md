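# Methods

## Model and assumptions

The analysis treats a d-channel time course X(u) as a path in ℝ^d.  Its
signature — the sequence of iterated integrals — characterizes the path up
to translation and monotone reparameterization of time.  The package uses
the truncation at order two: the antisymmetric part of the second-order
iterated integral, the lead matrix

A[i,j] = ½ ∮ (x_i dx_j − x_j dx_i),

which is the oriented area enclosed by the projection of the closed path
onto each coordinate pair.  A positive entry means the column channel
follows the row channel.  The object is meaningful for *cyclic* signals:
signals that revisit their values in a consistent order, periodic or not.
Reparameterization invariance is the point — two recordings of the same
cyclic process on different time scales yield the same lead matrix.

Assumptions worth stating:

- **Closure.** The integral formula presumes a closed path.  Each channel
  is first adjusted by a linear ramp so its endpoints agree, then
  mean-centered.  Closing before centering matters conceptually (the mean
  of the closed path is removed); the two orders differ only by a
  translation, to which A is invariant anyway.
- **One dominant cycle.** The leading eigenvector orders channels within a
  single common cycle.  When channels carry a second harmonic they vanish
  from the leading pair and appear in the second pair; the spectral
  summary therefore exposes the first two eigenvector pairs.
- **Direction ambiguity.** Eigenvector phases are defined up to a global
  rotation and a global sign; no statement about the absolute direction of
  the cycle is possible, only about the ordering.  All phase comparisons
  in the package (and its tests) are gauge-fixed accordingly, via
  `circular_rmse`, which minimizes over both gauges.

## Discretization and numerics

- The discrete lead matrix is the shoelace sum with wraparound,
  `½ Σ_k (x_i Δx_j − x_j Δx_i)` — exact for the piecewise-linear
  interpolant of the samples, so the only discretization error is the
  linear-interpolation error of the underlying signal.  At 10,000 samples
  per period-bundle the sinusoid closed form `n·π·a·b·sin(φ_i − φ_j)` is
  matched to ~2·10⁻⁴ relative error.
- Spectra are computed as `eigh(iA)`: iA is Hermitian, which guarantees
  exactly paired real eigenvalues ±μ and orthonormal eigenvectors.  The
  eigenvector reported for a pair is the one for +iμ, with its global
  phase fixed by rotating the largest-modulus component to argument 0
  (first occurrence on ties).  A leading magnitude below 10⁻¹² of the
  matrix scale flags the phases as undefined.
- Per-channel unit-variance normalization before the area sums is **off**
  by default and exposed as an option (`normalize=True`); it is required
  when channel amplitudes are not comparable, e.g. the two-amplitude
  offset-set regime.
- Warped (aperiodic) signals are produced by evaluating the analytic
  signal at warped times, never by resampling, so the identity warp is
  bitwise identical to the periodic generator and no interpolation error
  enters the reparameterization-invariance checks.

## Synthetic data: what it emulates, what it does not

The generator provides four single-run regimes (phase-shifted sinusoids at
a requested signal-to-noise power ratio, two offset sets with different
amplitudes, mixed first/second harmonics, monotone time-warped aperiodic
cycles) and a cohort generator shaped like a two-group, two-session
resting-state study: 15 + 32 subjects by default, 33 channels × 300
samples per run, 2 sessions × 2 runs.

Structure of the cohort model: group phase template (evenly spaced on the
circle) → persistent subject template (+ Gaussian jitter, std
`subject_jitter`, default 0.5 rad) → per-run phases (+ Gaussian jitter,
std `ordering_jitter_a/b`, defaults 0.1/0.4 rad).  The group contrast is
carried *only* by the run-jitter magnitude — amplitudes are identical
across groups — so any downstream discrimination must come from
lead-matrix structure.  With `contrast_channels` set, the patient-like
group's extra jitter is confined to designated channels, emulating a
contrast in which one group's ordering around a few regions is consistent
and the other's is variable.  SNR defaults to 20 (power ratio, white
Gaussian noise per channel); runs contain 6 cycles by default, the order
of magnitude of slow hemodynamic fluctuations over a 10-minute run.

Deliberately not modeled: hemodynamic response convolution, scanner drift,
physiological noise spectra, spatial correlation between regions, and any
image-space structure.  Passing tests therefore demonstrate that the
*pipeline* recovers planted ordering structure under white noise and phase
jitter — they do not certify performance on real fMRI, where noise is
structured and group contrasts are far subtler.

## Statistical components

- **Fingerprinting.**  1-nearest-neighbor under the cosine distance,
  trained on one session's runs and tested on the other, both directions;
  each subject can be correctly identified four times.  Features are raw
  lead-matrix vectorizations (no PCA).  Nearest-neighbor ties break to the
  lowest subject index.
- **Wilks' lambda.**  Univariate two-group Λ = SSW/SST per channel pair;
  ranking by ascending Λ equals ranking by descending one-way F.  Stability
  selection reranks on random half-subsets (drawn at the subject level,
  stratified by group, so runs of one subject never straddle the subset
  boundary) and counts top-k appearances.  Whole-data selection before
  split-half classification is supported for comparison but emits an
  explicit double-dipping warning.
- **Classification.**  Subject-level Monte Carlo half-splits; optional
  subsampling of the majority training group to the minority size.  PCA
  (10 components) and Wilks stability selection are fitted on the training
  half within each trial.  Classifiers: linear SVM (C=1), quadratic SVM
  (polynomial kernel, degree 2, coef0=1, C=1), LDA, QDA (regularization
  fallback 0.1 on singular covariance), and PLS-DA with 20 latent
  components (clipped to the training rank), ±1 class coding and decision
  threshold 0.  Confusion matrices are row-normalized percentages averaged
  over trials; overall accuracy is the class-size-weighted mean of the
  per-class rates, which equals the plain fraction correct at natural
  group sizes.
- **Graphs.**  Subject votes are signs of subject-mean normalized entries
  (each subject counts once; exact zeros abstain and are logged); edge
  weight is the vote proportion, ties resolve toward the positive
  (upper-triangle) direction.  Layers are longest-path depths after
  breaking cycles by repeatedly removing the lowest-weight edge on a
  cycle.  Normalization is by maximum absolute entry (Frobenius optional).

## Design choices that were genuinely open

- **Run-level features.**  PCA, selection and classification operate on
  runs (each subject contributes 4 feature vectors); subject identity is
  respected by all splits and subsets.  Subject-averaged features are the
  alternative; run-level keeps the fingerprinting and classification
  analyses on the same footing.
- **Wilks-vs-PCA ordering.**  Whether feature selection beats PCA
  reduction depends on where the discriminative signal sits relative to
  the dominant variance.  When dominant variance is concentrated on
  non-discriminative pairs and the contrast is weak and localized,
  stability-selected Wilks pairs clearly outperform 10-component PCA (the
  regression test plants exactly this geometry); with a diffuse contrast
  the ordering can reverse.  The package makes both protocols available
  rather than privileging one.
- **Quadrature and conventions** (shoelace sum; closing before centering;
  eigenvector gauge; tie-breaks by first occurrence / lowest index /
  lexicographic pair order) are each the deterministic choice; all are
  documented at the definition site.

## Problem sizes used in the checks

The acceptance computations use: a 47-subject cohort at full study
dimensions (33 × 300, 4 runs) for fingerprinting; 100 independent
16-subject null cohorts (10 channels × 150 samples) for classifier
calibration, one half-split trial each; 100 planted-feature datasets of
40 + 40 rows × 528 pairs at a 2-standard-deviation effect for selection
recovery, plus one 1,000-trial stability run; and 10,000-sample paths for
the closed-form area oracle.

## Known limitations

- Only order-two iterated integrals; no full signature, no streaming.
- Univariate Wilks' criterion (one discriminant direction); the
  multivariate generalization is out of scope.
- Classifier hyperparameters are fixed documented defaults; there is no
  hyperparameter search, so absolute accuracies on any particular dataset
  are not tuned.
- The cohort generator's group contrast is phase-only; amplitude or
  frequency contrasts would exercise different feature structure.
- NIfTI/image-space input is out of scope; the ROI table (33 regions,
  MNI centers, network labels) is shipped for bookkeeping, including two
  left-hemisphere entries with positive x coordinates reproduced verbatim
  from the source table rather than corrected.
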