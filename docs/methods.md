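# Methods

## The decoding problem

Two-class motor-imagery EEG decoding rests on event-related
desynchronization/synchronization (ERD/ERS): imagining a movement
attenuates band power of the sensorimotor mu and beta rhythms over
task-specific cortical patches, transiently and in specific frequency
bands.  A useful decoder therefore needs spatial filters (where), time
windows (when) and frequency sub-bands (which rhythm) simultaneously.
This package composes those three axes as sliding windows × CiSSA
sub-bands × CSP filters, fuses the resulting feature table, and scores a
linear SVM by stratified cross-validation.

## CiSSA sub-band filtering

Every single-channel series `s` of length `N` is embedded in the
`L × (N−L+1)` trajectory matrix of lagged windows.  Whereas classical SSA
diagonalizes the data-driven lag-covariance matrix, the circulant variant
replaces it with a circulant matrix built from the weighted
autocovariances

    γ_m = (1/(N−m)) Σ_t s_t s_{t+m},
    c_m = ((L−m)/L) γ_m + (m/L) γ_{L−m},     m = 0 … L−1.

The blend makes `c` symmetric, so the circulant matrix's eigenvalues —
the DFT of `c` — are real, and its eigenvectors are the unit Fourier
vectors regardless of the data.  Component `k` is therefore pinned a
priori to frequency `f_k = (k−1)·fs/L` with bandwidth `f_b = fs/L`.

Implementation choices:

* Elementary matrices are computed as projections `X_k = u_k u_kᴴ X` with
  an FFT along the embedding dimension; the circulant matrix is never
  formed.  Conjugate index pairs `{k, L+2−k}` are grouped before
  Hankelization so every reconstructed component (RC) is real; DC and (for
  even `L`) Nyquist are singletons.
* Hankelization of a rank-1 outer product is evaluated as a convolution
  divided by anti-diagonal counts, making the full decomposition
  `O(L·N log N)` per series and exact: the RC groups sum to the input to
  machine precision (the acceptance script measures ~1e−14 worst-case
  relative error over random series).
* A sub-band is the sum of RC groups whose centre frequency falls in the
  half-open interval `[f_lo, f_hi)`.  With the default grid (6–30 Hz,
  `f_b = 4` Hz, `L = 25`, `fs = 100` Hz) each band contains exactly one RC
  centred at its midpoint.  The out-of-band residual is retained by
  `extract_subbands` and simply discarded by the pipeline; no broadband
  pre-filter is applied.
* Finite-`L` leakage is real and documented rather than hidden: a tone at
  an RC frequency leaks ≤1% out of its band, but a tone exactly midway
  between RC centres (e.g. 10 Hz, which is also a band edge of the default
  grid) splits roughly 47/47% between the two adjacent bands.
* When `fs/f_b` is not an integer (e.g. 250 Hz recordings with 4 Hz
  bands), `L = round(fs/f_b)` is used, the realized width `fs/L` replaces
  the nominal one, and a warning is emitted; the band count stays the
  nominal one.

## CSP and log-variance features

Per (window, band), class covariances are means of per-trial
trace-normalized covariances `XXᵀ/tr(XXᵀ)`.  Filters solve the generalized
eigenproblem `Σ₁w = λΣ₂w` exactly as the Rayleigh quotient `Σ₁/Σ₂`
objective prescribes (not the `Σ₁/(Σ₁+Σ₂)` variant); a relative ridge of
`1e−8·tr(Σ₂)/C` keeps `Σ₂` well conditioned.  The `M` top and `M` bottom
eigenvectors are kept (`M = 2` by default → 4 features per cell),
rescaled to unit norm — the eigenproblem leaves scale free — with signs
fixed so the largest-magnitude coefficient is positive, and ties broken by
ascending index, making the output deterministic.  Features are natural
logs of population variances of the filtered trial; no variance
normalization precedes the log.  These conventions only shift/scale the
features affinely, which the margin classifier absorbs.

## Feature fusion

MIBIF ranks each of the `d = 2MBT` columns by `I(F_i; Ω) = H(Ω) − H(Ω|F_i)`
in bits.  The conditional entropy is estimated by class-conditional
univariate Parzen densities (Gaussian kernel, Silverman's rule on the
class subsample, with a narrow fallback kernel when a class subsample is
constant), converted to posteriors `p(ω|f)` by Bayes' rule with empirical
priors, and averaged over training points.  Estimates are clipped at 0.
Calibration on fixtures: a constant column scores exactly 0 bits, a
perfectly separating column ~1 bit, and a label-independent Gaussian
column < 0.05 bits in ≥95% of seeds at n = 280.

PCA uses the `1/(n−1)` covariance of mean-centred feature vectors and
keeps the top-`k` orthonormal eigenvectors (full SVD, deterministic
signs).  The feature–feature mutual-information diagnostic uses
leave-one-out Parzen entropy estimates, `I = H(X)+H(Y)−H(X,Y)` with
product kernels; leave-one-out removes the resubstitution bias that would
otherwise report ~0.16 bits between independent columns.

Both fusion stages are fitted on training rows only and applied to
held-out rows.

## Cross-validation protocol

Stratified k-fold (default 10) with shuffling driven by a single integer
seed; per-fold class proportions deviate from global by at most one
trial.  CSP banks, the fusion stage and the SVM (linear kernel, hinge
loss, `C = 1`, no class weighting) are refitted inside every training
fold — the windowing and CiSSA transforms are per-trial and label-free,
so they are computed once per dataset without leaking labels.  Reports
carry per-fold accuracies (%), their mean and (population) standard
deviation, the feature dimensions before/after fusion, and a
configuration fingerprint.

The diagnostics grid scores each (window, band, filter-rank) cell by the
cross-validated accuracy of an SVM on that single feature, over the whole
trial plus the `T` sub-windows; the fused 96-column feature vector uses
the sub-windows only.  Cell MIBIF values are computed on the full dataset
as a descriptive map.

## Synthetic ERD/ERS generator

Each trial is `Σ_r p_r · (env_{class,r} ⊙ source_r) + noise`:

* **Sources** are unit-variance white noise shaped in the frequency domain
  by a Gaussian amplitude mask (σ = bandwidth/4), giving exact spectral
  control without filter transients; ≥99% of power lies within the nominal
  band.
* **Patterns** `p_r` are fixed unit-norm channel vectors (seeded draws, or
  user-supplied forward-model columns).
* **ERD** multiplies class-2 source amplitude by `1 − erd_depth` inside
  the ERD window (default 0.5–2.5 s — the most discriminative imagery
  interval), so the within-window class-2/class-1 band-power ratio is
  `(1 − erd_depth)²`; the generator records realized per-trial source
  powers (whole-trial and within-window) as ground truth.
* **Noise** is per-channel `1/f` (exponent 1) shaped noise, scaled so the
  channel-average noise variance equals the class-1 signal variance
  divided by `snr`.

Defaults mirror the public recording conditions: `fs = 100` Hz, 3.5 s
trials, 140 trials/class, 17 sensorimotor channels, mu 10 Hz + beta 20 Hz
rhythms, `erd_depth = 0.7`, `snr = 1`, seed 7.  What the generator does
*not* emulate: volume-conduction forward models, eye/muscle artifacts,
non-stationary baselines, inter-subject variability, or rhythm frequency
drift.  Passing tests therefore demonstrate correctness of the machinery
and recoverability of a planted effect, not expected accuracy on real
recordings.

## Problem sizes in the test suite

The deep end-to-end checks run at the default conditions (280 trials, 17
channels; localization over 10 generator seeds at 70 trials/class and
snr 0.25, chosen so single-feature accuracies do not saturate and the
argmax cell stays identifiable).  Property suites that only need the
direction of an effect (accuracy monotone in ERD depth and SNR, chance
level at zero depth, CSP pattern recovery) use scaled replicates — 30–60
trials/class, 6–10 channels, 3–5 seeds, 5 folds — which measure the same
invariants at a fraction of the cost.

## Known limitations

* Mutual-information estimates depend on the Parzen bandwidth; Silverman's
  rule is adequate for the unimodal log-variance features but can misrank
  strongly multimodal features.
* CiSSA band edges are tied to the RC grid: rhythms centred on a band edge
  (e.g. 10 Hz with the default grid) split their energy between two bands.
  Decoding still works — both halves remain discriminative — but
  band-level attributions blur.
* The competition MAT importer epochs `[cue, cue + 3.5 s)` at face value
  and applies no re-referencing, detrending or artifact handling.
* Binary classification only; multiclass CSP extensions, shrinkage CSP,
  and data-driven window optimization are out of scope.
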