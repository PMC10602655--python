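# Methods

## Scope and design

`eegfc` implements a complete EEG functional-connectivity classification
pipeline for the three-way discrimination of Alzheimer's-type dementia
(AD), frontotemporal dementia (FTD) and healthy controls (HC):
synthetic 19-channel resting-state EEG with controllable ground-truth
coupling, band decomposition and feature extraction, four pairwise
connectivity measures, matrix thresholding and graph summaries, a
shallow convolutional classifier with conventional baselines, and a
repeated-split evaluation harness.  Because clinical recordings cannot
ship with the package, every empirical claim the test suite makes is
made against synthetic data whose coupling structure is known by
construction; what that does and does not establish is discussed at the
end of this note.

## Synthetic EEG generator

Each channel is a sum of five narrowband oscillations (delta, theta,
alpha, beta, low-gamma) plus white noise:

    x_i(t) = sum_b A_b * e_bi(t) * cos(2*pi*f_b*t + theta_i + w_bi(t)) + n_i(t)

with carriers f_b at 2.25, 6, 10, 21 and 37.5 Hz and per-band amplitudes
A_b = 0.6, 0.7, 1.0, 0.5, 0.3 (alpha-dominant, as in eyes-closed resting
EEG; arbitrary units).  The white-noise SD is 0.1 times the mean band
amplitude.

**Phase coupling.**  `w_bi` is *stationary* band-limited Gaussian phase
wander: white Gaussian noise mixed across channels, low-pass filtered at
0.6 Hz, and scaled to a per-channel variance of σ² = 4 rad².  The
cross-channel mixing uses a factor of the latent correlation
C = 2κ − κ², the exact variance law of the shared-driver mixture
φ = (1−κ)·own noise + κ·driver (pairwise phase-difference variance
2σ²(1−κ)²); the factorization is eigenvalue-clipped at zero so fully
coupled channels are bit-identical.  Each band's initial phase is shared
by all channels, so coupling is *zero-lag*: Pearson correlation sees
shared drivers (the volume-conduction-like regime) while the imaginary
part of coherency, by design, does not.

Why stationary wander rather than a phase random walk: a walk loses
zero-lag alignment within an epoch, which silences Pearson correlation
entirely; bounded wander keeps coupled pairs aligned while the large
variance (e^{−σ²} ≈ 0.02 phasor bias) still drives the uncoupled-pair
PSI toward zero as O(1/√T) through sampling decay.  The band limit keeps
FM sidebands inside each rhythm band (instantaneous-frequency SD
≈ σ·f_c ≈ 1.2 Hz) so that frequency wander does not convert into
spurious envelope fluctuations at the band-pass edges, which would
dilute the AEC.

The map from κ to measured PSI is monotone but *not* the identity.  At
10 s epochs, the calibration curve measured over 20 seeds is
approximately PSI ≈ 0.33, 0.39, 0.53, 0.78, 0.99 at κ = 0, 0.25, 0.5,
0.75, 1 (alpha band); at κ = 0 the median PSI over 200 s records is
≈ 0.06.  The regression tests assert monotonicity (Spearman ≥ 0.95) and
the locked/uncoupled endpoints, not the intermediate values.  σ² and the
cutoff were calibrated jointly against the uncoupled-decay and
monotonicity contracts and then frozen.

**Envelope coupling.**  The modulators e_bi are built from unit-variance
Gaussian latents correlated across channels with the envelope template
rho (same Cholesky construction), low-pass filtered at 0.7 Hz,
re-standardized, then mapped through softplus(1.5 + 0.5·g).  The
softplus operates in a near-linear regime, so measured amplitude
envelope correlation (AEC) tracks rho with a mild attenuation: a target
of rho = 0.8 yields a median measured AEC of ≈ 0.76 over 60 s (20
seeds).  Exact attainment is deliberately not promised; tests use
acceptance bands.

**Group structure.**  All groups share a baseline kappa = rho = 0.2 in
theta, alpha, beta and low-gamma.  The FTD-like group is elevated by the
`effect_size` on all frontal–temporal channel pairs, the AD-like group
on the disjoint parietal/occipital block, the HC-like group is baseline
everywhere; `effect_size = 0` makes the three groups statistically
identical.  The delta band is near-degenerate for every group
(kappa = rho = 0.95 on every pair) so that delta connectivity matrices
are uniformly high and carry no class information — mirroring the
degeneracy observed in the clinical delta band — and delta is excluded
from classification grids by default.

**Seeds.**  One master seed; per-subject seeds derive from
`SeedSequence(master, spawn_key=(subject_index,))`, so subjects are
independent but every recording is bit-reproducible.

An optional per-subject *severity* covariate (uniform on [0.5, 1.5],
multiplying the subject's effect blocks; 0 for controls) supports
descriptive probability-vs-severity reports.

## Feature extraction

Recordings are cut into non-overlapping 10 s epochs (trailing partial
segments discarded); all filtering is zero-phase 4th-order Butterworth
(forward–backward), which preserves instantaneous phase for the PSI.
Band edges: delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, low-gamma
30–45, broadband 0.5–45 Hz.

*Spectrograms*: per-channel STFT with a 1 s Hanning window and 50% hop
(19 frames per epoch), log magnitude with a machine-epsilon floor,
frequency axis cropped to 0.5–45 Hz, bilinear resampling to 224 × 224,
min-max scaling to [0, 1]; constant inputs map to the all-zero image.

*Conventional features*: per channel, the time-domain energies (sums of
squared samples) of the five band-filtered signals plus min, max, mean,
median, variance, SD, Fisher excess kurtosis and (biased moment)
skewness of the unfiltered epoch; flattened channel-major, 13 features
per channel.

## Connectivity measures

All four measures produce a symmetric channels × channels matrix per
epoch; phase/envelope measures receive the band-filtered signal
(broadband counting as a band).

* **PSI** |T⁻¹ Σ exp(j(φx − φy))| with phases from the Hilbert analytic
  signal; in [0, 1], 1 = strict locking.
* **ImCoh** |Im(Pxy)| / sqrt(Pxx·Pyy) per Welch bin (1 s Hanning
  segments, 50% overlap), averaged over the bins strictly inside the
  band.  The square-root denominator is the standard coherency
  normalization and keeps the measure in [0, 1]; a variant without the
  square root is available behind a flag but is not bounded by 1 and is
  off by default.  Zero-lag (volume-conduction-like) coupling yields 0.
* **Corr** Pearson correlation of the two series.
* **AEC** Pearson correlation of the Hilbert envelopes after trimming 5%
  of samples at each end (filter/Hilbert transients); no
  orthogonalization is applied.

Diagonals are fixed by convention (PSI/Corr/AEC 1, ImCoh 0) and are
excluded from thresholding and graph analysis.

## Thresholding and graph metrics

Absolute thresholding zeroes off-diagonal entries with |value| below the
cutoff (default 0.7); proportional thresholding keeps the top p% of
upper-triangle entries ranked by |value| (quota = round(p/100 · 171) for
19 channels; ties straddling the cut are all kept and the excess is
logged); retained weights keep their sign.  Matrices fed to classifiers
are z-score normalized over the retained off-diagonal entries
(population SD); zeroed entries stay zero, and a fully-emptied matrix is
passed through unnormalized.

Graphs are binarized (edge wherever a retained entry is nonzero) and
summarized by mean degree, mean Watts–Strogatz local clustering
(degree < 2 contributes 0), global efficiency (mean inverse shortest
path over pairs; disconnected pairs contribute 0) and node-mean
*unnormalized* betweenness centrality.  The betweenness convention was
chosen because the reported clinical-scale values (≈ 3–13) are only
consistent with unnormalized counts.  Metrics are computed with
networkx and cross-checked against python-igraph in the tests.

## Classifiers

The shallow CNN is implemented directly in numpy (no deep-learning
framework is required): conv(5 × 5, 50 filters, same padding) → batch
norm → ReLU → 2 × 2 max pool (floor mode) → conv(5 × 5, 50) → batch norm
→ ReLU → flatten → dense(3) → softmax.  The head is the smallest viable
choice consistent with a "shallow" design; a single pooling stage joins
the two blocks.  Training uses SGD with momentum 0.9, learning rate
0.001, batch size 128, at most 50 passes, cross-entropy loss, validation
every 8 iterations, early stopping after 20 consecutive checks without
validation-loss improvement, and restoration of the best-validation
checkpoint.  Convolutions are im2col matrix products in float32 with
reused scratch buffers; runs are deterministic given the seed.
Connectivity matrices enter at native 19 × 19 (z-scored); spectrograms
at 224 × 224.

Baselines are scikit-learn LDA (no shrinkage), RBF-SVM (C = 1,
gamma = 1/n_features) and kNN (k = 5) on standardized conventional
features, with stratified 10-fold cross-validation reported alongside
the fit.

## Evaluation protocol

Epochs are split 70/15/15 into train/validation/test, stratified by
class, ten times with independent seeds; the median of each test metric
over the ten repeats is reported.  Epoch-level splitting is the default
and mirrors the reference protocol, but it lets epochs of one subject
appear on both sides of a split; a subject-level mode is provided and is
the recommended setting for claims about generalization to unseen
subjects.  Metrics are one-vs-rest accuracy, sensitivity, specificity,
precision and F1 per class (F1 = 0 when precision + sensitivity = 0),
macro averages, and overall accuracy as plain fraction correct (checked
against the per-class TP bookkeeping on every run).

## Problem sizes used by the shipped tests

The parameter-recovery check uses 30 subjects per group × 20 epochs
(1,800 epochs), effect size 0.3, fixed seed, CNN on unthresholded
alpha-band AEC matrices over 10 splits, compared against all three
baselines on conventional features.  Null controls use 10 subjects per
group × 6 epochs at effect 0 plus label permutation on toy data.
Integration tests of the experiment grid run at 5 subjects × 4 epochs
with 2 repeats.

One nuance of absolute thresholding on synthetic data: the per-epoch
AEC estimator has a standard error of roughly 0.25 at 10 s epochs, so
even though the planted couplings sit below 0.7, the estimator's upper
tail occasionally crosses the cutoff on elevated pairs.  An absolute
0.7 cut therefore leaves sparse but weakly discriminative matrices
rather than empty ones; the tested (and observed) property is that
classification degrades markedly relative to unthresholded matrices,
not that it collapses exactly to chance.

## A note on broadband AEC

For this generator, AEC computed on the 0.5–45 Hz broadband signal is
uninformative: the Hilbert envelope of a sum of discrete carriers is
dominated by inter-carrier beating rather than by the slow modulators,
so the planted envelope correlation does not survive broadband mixing.
Real EEG, with continuous 1/f spectra and a dominant rhythm, does not
share this pathology.  The headline recovery experiment therefore runs
on the alpha band, where the planted coupling is directly measurable;
broadband PSI and Corr remain informative.

## Numerical choices and degenerate inputs

Hilbert phases/envelopes are FFT-based; edge transients are excluded
where a test asserts tight tolerances.  Correlation of a constant series,
coherency of a zero-power band, the phase of an all-zero signal, and
z-scoring of fewer than two distinct retained values raise errors rather
than returning NaN.  Positive-semidefiniteness of coupling matrices is
enforced by eigenvalue clipping at 1e-10 with row renormalization.
Proportional-threshold ties are resolved by keeping every tied value.

## What passing tests show — and what they do not

The synthetic data establishes that the pipeline is *correct*: each
measure matches its analytic values and independent oracles, planted
coupling is recovered monotonically, classifiers find exactly the
structure the generator encodes and nothing under null conditions, and
the threshold/graph bookkeeping is exact.  The generator does not model
1/f background spectra, artifacts, volume conduction (beyond zero-lag
mixing being absent by construction), non-stationarity, inter-subject
anatomical variability, or realistic class overlap; accuracies obtained
on it are therefore statements about the pipeline, not estimates of
clinical performance, and are not comparable to accuracies reported on
clinical recordings.
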