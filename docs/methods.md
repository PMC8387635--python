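# Methods

This note documents the models, conventions and numerical choices behind
`emonet`, and what the synthetic benchmark does and does not establish.

## Signal conditioning

Continuous EEG is processed in a fixed order: band-pass 1–45 Hz →
common-average re-reference → downsample to 250 Hz → last-150-s epoching
into non-overlapping 1-s windows. The order is recorded in each output's
metadata. Filters are zero-phase windowed-sinc FIR (Hamming); the
transition bandwidth is `min(low, 0.25·low + 2)` Hz, which yields ~3,300
taps for a 1 Hz edge at 1,000 Hz. A linear-phase kernel applied once in
centred ("same") alignment is already zero-phase, so no forward-backward
pass is needed; signals are reflect-padded by one kernel length to tame
edge transients. Downsampling is polyphase with an exact integer ratio
where possible (1,000 → 250 Hz is /4). ICA-based artifact removal is a
pluggable hook that defaults to pass-through: the synthetic generator
plants no ocular or muscle artifacts, and a trained component classifier
is outside this package's scope; real-data users supply their own cleaner.

## Source model

The inverse operator is the minimum-norm kernel K = Lᵀ(LLᵀ + λI)⁻¹ with
λ = λ_rel·tr(LLᵀ)/n_sensors and identity noise covariance, standardized
row-wise by √((KL)_ii) (sLORETA). Sources have fixed orientation — one
scalar per source. Defaults: λ_rel = 1/9, the SNR = 3 convention of common
source-analysis software; it is configurable because the reference
software's exact regularization is not published with the analysis.
Standardized minimum-norm estimates localize a noiseless point source with
zero error; the test suite verifies this by exhaustive scan (λ = 0, where
the property is exact).

Region time courses are arithmetic means of member-source time courses
over a source→region map (Desikan-Killiany, 68 regions in the faithful
configuration). Parcellation is applied to broadband signals before band
decomposition; both operations are linear, so the order is immaterial up
to filter commutation, and the cheaper order is used.

## Connectivity features

Per 1-s epoch and band, the feature block is the strict upper triangle of
the 68×68 Pearson matrix; the five blocks concatenate δ→γ into 11,390
features. Band filtering of 1-s epochs reflect-pads by one epoch length;
the kernel length is capped at three epoch lengths. Two fidelity caveats
are inherent to the 1-s convention and deliberately reproduced: the delta
band has fewer than four cycles per window, and band-limited signals have
far fewer effective samples than 250, so single-epoch correlations are
noisy. Pearson r uses population (1/n) normalization — immaterial to r —
and zero-variance regions produce zeroed rows/columns with a logged
warning rather than NaN. Whether band filtering is applied per epoch
(default) or to the continuous region signal is a pipeline option.

## mRMR selection

Features are discretized by equal-frequency binning into 3 bins (the
convention of the original mRMR formulation; configurable). Mutual
information is the plug-in estimate on empirical joint counts, in bits.
The greedy rule is the difference (MID) form — step k maximizes
I(f;c) − (1/|S|)Σ_{s∈S} I(f;s) — with the quotient (MIQ) form behind a
flag; ties break toward the lowest feature index so selection is fully
deterministic. Note one consequence verified in testing: when a selected
feature equals the class label exactly, every candidate's MID score
collapses to I(f;c) − I(f;c) = 0, so "the duplicate is never re-picked" is
only guaranteed when the remaining candidates have positive net score.

## Classification protocol

RBF-SVM over the printed grid (g ∈ 0.5…4.0 step 0.5; C ∈ 10⁻²…10² decade
steps; 40 pairs), repeated stratified 10-fold CV with per-repeat
reshuffling; the report retains every fold accuracy. Features are scaled
to zero mean and variance 1/D before the kernel, making the exponent
g·‖x−z‖²/D — the dimension-normalized RBF convention (a g-multiple of the
common "scale" gamma heuristic). This choice is deliberate: with plain
unit-variance scaling in D = 10 selected features, the entire printed grid
sits in the narrow-kernel regime and even a trivially separable problem
cannot be classified reliably, whereas the normalized convention keeps the
grid in the useful range regardless of D.

Two protocols are provided because they answer different questions.
`nested` (default) fits mRMR, scaling and the hyperparameter grid (inner
stratified 3-fold CV) on training folds only — an unbiased estimate.
`pooled` fits selection and scaling once on all samples and reports the
best grid point's outer-CV mean — the "top features, then cross-validate
under optimal parameters" protocol, which is optimistically biased on null
data. The test suite pins the gap between the two on pure-noise features
as a regression test of the leakage mechanism. Samples are pooled across
subjects within a scenario; folds can optionally be grouped by song to
avoid splitting correlated epochs of one song across folds.

## Rating-scale statistics

Scores are compared between scenarios per (scale, item, emotion). The
design is within-subject, so the paired t-test is the default (independent
mode available). The 95% CI is on the raw mean difference, oriented
non-negative as such comparisons are conventionally printed. Two effect
sizes are computed: the pooled-SD Hedges's g (reported magnitude, the
printed-table analogue) and the paired-difference d_z; the printed tables
do not disclose which definition they use, so both are carried and the
pooled variant is labelled the analogue. `p` is rendered "p < 0.01" below
0.01, else "p = x.xx".

## Synthetic generator

Lead fields are unit-norm Gaussian columns with a covering source→region
partition (first one source per region, remainder round-robin) — no head
geometry or BEM solve is emulated. Source signals are region-level: each
region's signal is the sum of five unit-variance band-limited Gaussian
components (equal band power; real EEG's 1/f shape is not emulated).
A planted coupling (i, j, band, ρ) replaces region j's band component by
√(1−ρ²)·x_j + ρ·x_i in the designated (class, scenario) only, making the
expected band-limited Pearson correlation of the pair ≈ ρ — a closed-form
check used throughout the tests. All sources of a region carry the
region's signal, so parcellation recovers the planted structure exactly.
Sensor data are gain·sources plus white noise with RMS(signal)/RMS(noise)
= `noise_snr` (default 3, matching the λ_rel = 1/9 inverse default).

Ratings are truncated normals at configured means/SDs, rounded to each
scale's integer grid and clipped to its bounds (SAM 1–9, self-rating 1–4,
third-party 1–10). Default means are the study's reported condition means;
the per-condition SDs are not reported, so the defaults (1.5 / 0.5 / 0.7
score points) were chosen once as plausible spreads relative to each
scale's range. The two songs of a class are i.i.d. realizations of the
class model; within-class song heterogeneity is not modelled.

Session defaults mirror the study design: 16 subjects, 2 scenarios, 3
classes × 2 songs, 3-minute songs at 1,000 Hz, 59 sensors.

## Problem sizes in the shipped benchmark

The planted-effect benchmark runs the full 68-region feature space
(11,390 features) with one 104-s song per class and scenario at 250 Hz —
100 epochs per class and scenario — γ-coupling ρ = 0.8 per class in the
stronger scenario and 0.5 in the weaker, nested protocol, 5 repeats of
10-fold CV; its null twin sets ρ = 0. Calibration checks use 1,000
simulated rating tables (type-I error, CI coverage), 100 random
selection instances against an exhaustive greedy oracle, and 20 random
lead fields for the localization property. These sizes are the package's
benchmark configuration; every count is a parameter.

## What passing does and does not show

Passing shows the chain is internally correct: planted effects of known
strength survive preprocessing, inverse mapping, parcellation and band
decomposition, and are recovered by the selection/classification stack at
rates far above a calibrated null; and the statistics match their closed
forms and nominal error rates. It does not show that real EEG would yield
the study's accuracy figures: the generator omits 1/f spectra, volume-level
artifacts, realistic lead-field correlation structure, inter-subject
variability and song heterogeneity, all of which make real decoding
harder. Reported-table numbers enter only as generator means — recovering
them demonstrates calibration of the generator plus correctness of the
statistics, not an independent replication.

## Known limitations

* Phase-based connectivity (PLV, phase-slope, partial directed coherence)
  is out of scope.
* No bad-channel interpolation, ICA, or impedance handling; EDF export is
  16-bit with 1-s records and integer sampling rates.
* `pooled` mode is provided for protocol faithfulness and should not be
  used to report generalization performance.
* The delta band within 1-s epochs is under-resolved by construction (see
  above).
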