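# Methods

`earmotion` implements an end-to-end analysis for single-channel ear-EEG
emotion experiments: a subject watches ~2-minute affective video clips
drawn from the five quadrants of Russell's Circumplex model (low/high
valence × low/high arousal, plus neutral), rates each clip on the SAM
1–9 valence and arousal scales, and the analysis asks which features of
the mastoid-channel EEG discriminate the self-reported emotion levels.
Because no public recordings accompany this design, the package ships a
first-class synthetic cohort generator with known, recoverable effects;
every downstream stage is developed and tested against it.

## Synthetic cohort generator

Each session contains a 2-minute eyes-closed (EC) and eyes-open (EO)
baseline followed by the videos in a per-subject randomized order,
sampled at 250 Hz in microvolts. The signal model per block is

* five band-limited Gaussian oscillation components (δ 1–4, θ 4–8,
  α 8–12, β 12–30, γ 30–42 Hz), synthesized by FFT spectral shaping
  with 0.5 Hz raised-cosine edges so neighbouring bands do not leak
  into each other. Default band powers are δ 25, θ 16, α 20, β 9,
  γ 4 µV² — ear-EEG-scale amplitudes (signal SD ≈ 9 µV) that stay well
  inside the 100 µV artifact-rejection bound;
* a 1/f pink background (5% of total power) restricted to 1–45 Hz;
* a broadband white "complexity" component (8% of total power by
  default) whose weight is scaled by a per-class complexity factor with
  the oscillation weight adjusted so total power is unchanged — this
  moves entropy/complexity features without moving band power;
* class effects as per-band power multipliers active during each video;
* EC multiplies α power by a configurable factor (default 2.0) relative
  to EO and the videos, reproducing the classic eyes-closed alpha
  blocking contrast used as a physiological-validity check.

Two stochastic components model the between-stimulus variability of
real EEG, without which synthetic class effects separate perfectly and
rank-based comparisons degenerate into tie-breaking:

* canonical-band power jitter — each block draws an independent
  log-normal factor per band, SD {δ 0.4, θ 0.35, α 0.5, β 0.1, γ 0.1}
  on the log scale. The slow and alpha bands are the labile ones
  (vigilance and attention drift); artifact-free fast-band power is
  comparatively stable. This hierarchy is what makes absolute β/γ power
  the cleanest carrier of planted fast-band effects, as observed in
  real recordings, rather than derived shape features (Hjorth
  mobility, spectral ratios) which pool the noisy slow bands;
* within-band redistribution — each canonical band is synthesized as
  its sub-bands (α1/α2, β1/β2/β3, γ1/γ2) whose bandwidth shares are
  re-weighted by an independent log-normal factor (SD 0.25),
  renormalized so the parent-band power keeps the coherent factor.
  This emulates individual peak-frequency drift and decorrelates
  sub-band features from their parent, giving the parent band a genuine
  pooling advantage.

SAM ratings are class prototypes — LV–HA (2,8), HV–HA (8,8), LV–LA
(2,2), HV–LA (8,2), Neutral (5,5) — plus Gaussian noise (SD 1.0),
rounded and clipped to [1, 9]. Default class effects raise β/γ power by
40% with complexity ×1.2 in high-arousal classes and raise α by 20%
with β/γ ×0.9, complexity ×0.9 in low-arousal classes; the effect
magnitudes are free parameters of the generator, not calibrated to any
real recording.

Artifacts are injected at configurable per-minute Poisson rates
(defaults 0.5 jumps, 0.3 EMG bursts, 0.3 drift epochs): amplitude
jumps are 120–250 µV boxcars of 0.2–0.8 s; EMG bursts are 30–45 Hz
noise of 20–35 µV SD over 1–5 s with a Tukey taper; drift epochs are
0.5–2 Hz sinusoids of 40–90 µV over 5–15 s. Every event is logged
(type, onset, duration, amplitude) so tests can assert detection.
Channels are generated independently per electrode of the default
4-electrode montage (R4a, AF7, AF8, L4a); no inter-channel correlation
structure is modeled because the analysis is single-channel (R4a).

Reproducibility: subject k's generator is seeded by a SHA-256 hash of
(cohort seed, subject id) reduced to 64 bits, so cohorts are bit-stable
across runs and subjects are mutually independent.

What the generator does **not** emulate: volume-conduction or any
biophysical head model, blink/ECG artifact morphology, non-stationarity
within a block beyond the artifact events, rating biases other than
additive noise, and inter-channel correlation. Passing recovery tests
therefore show that the pipeline detects band-power and complexity
contrasts of the injected kind at realistic SNR — not that it would
perform identically on real recordings.

## Preprocessing and quality control

Filtering is a zero-phase (forward–backward) 4th-order Butterworth
band-pass at 1–45 Hz followed by a zero-phase 50 Hz IIR notch
(Q = 30), applied per channel. Signals are segmented into
non-overlapping 1-s windows; a segment is rejected iff its maximum
absolute amplitude exceeds 100 µV on any channel, a trailing partial
second is dropped, and retained segments are concatenated into the
cleaned signal with the retention index = retained/total.

Six normalized QC metrics score each video on 0–100 (higher = cleaner);
a video enters analysis only if **all** metrics reach the gate (60):

| metric | statistic | mapping |
|---|---|---|
| jump_rate | per-minute count of sample-to-sample jumps > 25 µV | 100·max(0, 1 − count/30) |
| amplitude | fraction of samples with abs. value > 100 µV | 100·max(0, 1 − frac/0.05) |
| peak_to_peak | fraction of 1-s segments with p2p > 150 µV | 100·max(0, 1 − frac/0.05) |
| hf_contamination | P(30–45 Hz)/P(1–45 Hz) | 100·max(0, 1 − max(0, ratio − 0.5)/0.3) |
| lf_contamination | P(1–4 Hz)/P(1–45 Hz) | 100·max(0, 1 − max(0, ratio − 0.6)/0.3) |
| retention | 1-s segment retention index | 100·retention |

All constants are exposed in `QCConstants`. Excluded videos are
bucketed into mutually exclusive reason categories (event-rate,
HF, LF, combined, retention-only) that sum to the total exclusions.

SAM ratings are binned per dimension: 1–3 → label 0 (low), 4–6 → 1
(mid), 7–9 → 2 (high). Class balancing selects, per subject, V =
min-over-(subject, label) QC-passing videos per label (keeping the
highest-mean-QC videos, ties by video id) and a global per-video window
quota E_min = min over retained videos of available feature windows
(the chronologically first E_min windows are used). A subject with no
video for a required label is excluded from that dimension.

## Feature extraction (39 features)

Features are computed on 15-s windows with a 2-s shift over each
video's cleaned signal. The spectral group (27) uses Welch's method
with a Hamming taper, `nperseg = min(N, max(128, fs))` and 50% overlap:
absolute spectral power (ASP) via trapezoidal integration over the
closed band interval, relative power RSP = ASP/TotalPower where
TotalPower sums the five canonical (non-overlapping) bands, and two dB
ratios ABR = 20·log10(0.6·β/γ) and AGR = 20·log10(0.6·α/γ). The closed
integration interval makes sub-band powers exactly additive to their
parent band (a half-open grid at 1 Hz resolution would lose a full bin
per band); a config switch provides the literal all-12-band TotalPower
and the name-faithful α/β variant of ABR. The non-linear group (9):
Hjorth Activity/Mobility/Complexity, zero-crossing rate per second,
Petrosian and Higuchi (k_max = 10) fractal dimensions, LZ76
Lempel–Ziv phrase count on the median-binarized window normalized by
n/log2(n), permutation entropy (order 3, delay 1, z-scored, ties by
index order, normalized by log2(3!)), and sample entropy (m = 2,
r = 0.2 on the z-scored window, Chebyshev distance, templates from the
first N−m positions). The statistical group (3): coefficient of
variation, Fisher–Pearson skewness, excess kurtosis.

Numerical safeguards: power denominators floored at ε = 1e-12 µV²,
the CV mean floored at 1e-6 µV, sample entropy capped at ln(#template
pairs) when no (m+1)-match exists, and degenerate (near-constant)
windows return flagged zeros instead of NaN — the output contains no
NaN/Inf by contract, enforced by fuzz tests. Sample entropy and LZ76
parsing run as numba kernels (the all-pairs template count is O(n²) at
n = 3750).

## Statistical screening

Per subject and dimension, each feature is tested with a tie-corrected
Kruskal–Wallis omnibus across labels {0,1,2} (α = 0.05); significant
features proceed to two-sided Mann–Whitney contrasts (low-vs-mid,
mid-vs-high, low-vs-high) with Cliff's δ = (#(x>y) − #(x<y))/nm.
BH-FDR is applied over the feature × contrast family actually tested
within one (subject, dimension) — the narrowest defensible family. For
standalone binary comparisons a parametric branch (Welch t, pooled-SD
Cohen's d) fires when Shapiro–Wilk holds on both samples and Levene
holds jointly (all at α = 0.05). Effect-size classes: |δ| ≥ 0.474
large, ≥ 0.33 medium, ≥ 0.147 small (|d| ≥ 0.8/0.5/0.2).

The cohort-level screen keeps a (feature, contrast) cell when an
FDR-significant large effect occurs in ≥ 30% of subjects and ≥ 50% of
those subjects share the effect direction. Survivors are ranked by

    score = −log10(max(median_p, 1e-12)) × normalized_effect × consistency

with median_p the median raw Mann–Whitney p over affected subjects
(the BH-adjusted p gates significance; the raw p feeds the score),
normalized_effect the median |δ| over affected subjects divided by the
large-effect threshold 0.474 (so values above 1 indicate
beyond-threshold effects), and consistency the modal-direction
fraction among affected subjects. Subject-level exclusion rules:
raters deviating ≥ 3 points from the leave-one-out group mean on
> 30% of videos (either dimension), and feature outliers whose mean
feature values sit > 2 group SDs from the group mean for > 30% of the
39 features.

## Classification and attribution

The binary task keeps labels {0, 2} (low vs high) of the balanced
selection. The classifier is a feedforward softmax network trained with
categorical cross-entropy + optional L2 (λ ∈ {0, 5e-4}), Adam at
lr 1e-3, batch size ∈ {128, 256} (clamped to the dataset), early
stopping on validation loss with patience 20 and max 200 epochs,
restoring the best weights. The hyperparameter grid is 14 node
arrangements — all strictly decreasing width tuples over
{16, 32, 64, 128} with 1–3 hidden layers (4 + 6 + 4) — × ReLU/tanh ×
2 batch sizes × 2 λ = 112 configurations. Evaluation uses stratified
10-fold splits rotated through 6 train / 2 validation / 2 test
assignments; 5 rotations cover every fold as test once, realizing the
60/20/20 split. Standardization uses training-fold statistics only.
The selected model is the test-accuracy argmax among configurations
with training accuracy ≥ 0.90 (ties: fewer parameters, then grid
order), falling back to the overall argmax with a warning flag.
Baselines (RBF-SVM, kNN k=5, logistic regression max_iter=1000) use the
same rotations, fitted on the training folds.

Attributions are taken w.r.t. the pre-softmax class logit (avoids
softmax saturation): Gradient × Input |x_i · ∂y_c/∂x_i| and Integrated
Gradients (x_i − x'_i)·∫∂F/∂x_i, the path integral approximated by a
50-step midpoint Riemann sum from a zero baseline in standardized
feature space (≈ the training-fold feature mean). Per subject,
attributions are computed on the training split of the best rotation,
averaged over the rows of each class, and min–max normalized across
the 39 features per class. A subject's feature set is those with
normalized relevance > 0.5 in both classes, topped up to ≥ 8 by
min-over-class relevance; group tables retain features selected in
≥ ceil(30% × subjects) subjects and report per-class cumulative sums
with Total = Low + High.

## Problem sizes used by the test suite

The acceptance-style recovery and null-control runs use scaled-down
cohorts chosen as the package's own test conditions: recovery — 16
subjects, 4 videos per class of 17 s (2 windows per video), β/γ power
×1.5 in high-arousal classes, an 8-configuration sub-grid with a
single fold rotation, 10 seeds; null control — 8 subjects, 5 videos
per class of 16 s (one window per video), no injected effect, 50
seeds. The full 112-member grid, 5 rotations and 2-minute videos
remain the defaults for real-scale runs.

The scaled-down geometry follows from a property of window-level
testing worth stating explicitly: the screen treats feature windows as
exchangeable samples, but overlapping windows from one video are
near-duplicates of that video's realized band power, so the effective
sampling units are videos. With very few videos per label this
pseudoreplication lets between-video noise masquerade as effect (and
saturates the Mann–Whitney p of genuinely affected features at its
combinatorial floor, reducing score ranking to tie-breaking). The test
cohorts therefore use many short videos — one window per video for the
null control, two for recovery — so that units are plentiful and
approximately independent. The same caveat applies to real designs
with few long stimuli per condition.

## Known limitations

* The QC metric internals, the normalized-effect definition, the
  14-arrangement reconstruction, the fold-rotation reading of the
  60/20/20 + 10-fold protocol, and the IG baseline/step count are
  documented design choices where the underlying experimental
  description is underspecified; all are config-exposed.
* Sliding windows may span a rejection splice in the concatenated
  cleaned signal; window counts treat the cleaned signal as contiguous.
* Splits are segment-level; heavily overlapping windows from the same
  video can share folds, which inflates absolute accuracies. A
  video-grouped split is not implemented; within-subject comparisons
  between classifiers remain valid.
* The generator's effect sizes and noise SDs are free parameters; none
  of the quantitative results on synthetic cohorts transfer to real
  recordings.
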