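# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `eegmark`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Windowing and calibration

Recordings are segmented with a sliding window of 256 samples and 50 %
overlap (hop = 128). A trailing partial window is discarded rather than
zero-padded: the nonlinear features assume fixed length, and padding would
bias both entropy and curve-length statistics. Each window carries its
parent `recording_id`, which is what makes recording-stratified folds and
recording-local DFI differencing enforceable downstream.

Amplitude thresholds are expressed in µV, but raw file values in the
supported dialects are ADC units. A multiplicative `calibration` factor
(µV per unit, default 1.0) is applied at read time, and feature extraction
warns when every recording still has calibration 1.0 — running µV
thresholds on unconverted ADC units silently distorts the wave-energy
features. An optional preprocessing hook applies a 4th-order zero-phase
Butterworth band-pass (default 0.5–70 Hz, matching common clinical
acquisition filtering); it is off by default, and no further denoising is
performed.

## Pathological wave energy (SpikeE, SharpE)

A candidate transient is a strict local maximum (`x[i−1] < x[i] > x[i+1]`).
Its support is found by walking from the peak in each direction while
samples strictly decrease; the walk stops at the first non-decrease (a tie
counts as the minimum) or at the window edge, which is treated as a
trough. On tie-free signals this is exactly the nearest strict local
minimum; the tie rule makes the procedure deterministic and keeps the
supports of smooth pulses on a flat background exact.

Measurements on the triple (left trough, peak, right trough):

- duration = trough-to-trough width in ms,
- amplitude = peak value − mean of the two trough values (a
  prominence-like measure, robust to baseline drift),
- energy = Σ x_j² over the closed support (µV²).

Classification applies the clinical bands spike-first:

| class | duration (ms) | amplitude (µV) |
|---|---|---|
| spike | [20, 70) | > 50 |
| sharp wave | [70, 200] | [100, 200] |

The printed clinical ranges meet at 70 ms, so the boundary needs a
deterministic owner; the spike interval is right-open and 70 ms belongs to
the sharp class. The sharp upper amplitude bound is "approximately" 200 µV
clinically and is therefore configurable (including +∞). Within one class,
events are accepted greedily left-to-right and a candidate whose support
overlaps an already-accepted same-class support is dropped, so same-class
supports are pairwise disjoint and energies are sums over disjoint index
sets. Only upward transients are detected by default; `detect_negative`
additionally scans the sign-flipped signal. No spectral gate is applied:
the frequency equivalents of the duration bands are informative, not an
extra criterion. The per-class energy is the sum of each accepted event's
squared-sample energy over its support, summed over events.

## Permutation entropy

For embedding dimension m and delay τ, each of the M = n − (m−1)τ delay
vectors is reduced to the permutation that sorts it ascending; equal
values are ranked by earlier index (stable sort), which makes the
estimator deterministic on data with ties. PE is the Shannon entropy of
the pattern frequencies in natural log units, in [0, ln m!]; an optional
flag normalizes by ln m!, but unnormalized PE is what the feature table
carries. Defaults m = 3, τ = 1: with 256-sample windows this leaves 254
vectors against 6 possible patterns — adequate sampling, whereas m ≥ 5
(120+ patterns) would starve the estimate at this window length.

## Higuchi fractal dimension

For scale k and offset m ∈ 1..k the normalized curve length is

    L_m(k) = (1/k) · [ Σ_{i=1..⌊(N−m)/k⌋} |x(m+ik) − x(m+(i−1)k)| ] · (N−1)/(⌊(N−m)/k⌋·k)

(1-based indexing). ⟨L(k)⟩ averages L_m(k) over the k offsets, excluding
offsets whose subsequence has fewer than two points; HFD is the negated
slope of the unweighted least-squares fit of ln⟨L(k)⟩ on ln k over
k = 1..k_max (default 10, requiring n ≥ 2·k_max). A constant signal has
zero curve length at every scale; the estimate is defined as 0.0 with a
warning rather than an exception, so degenerate windows do not abort batch
extraction. On an arithmetic ramp ⟨L(k)⟩ = (N−1)/k exactly, giving
HFD = 1; white noise gives ≈ 2 — both are asserted in the tests.

## Dynamic feature increment

DFI is computed per recording from the min–max-normalized sequences of the
four base features: DFI_t = Σ_f |f̄(t) − f̄(t−1)| with DFI_0 = 0 at each
recording start, bounded in [0, 4]. The prose definition ("normalizing,
taking the absolute value, and summing the first-order differences of each
feature") is read as per-feature absolute values summed over features —
the alternative |Σ_f Δf̄| is available via `convention="abs_sum"`. DFI is
per-window (the sum runs over features, not over time) because it feeds
the classifier one row per window. Normalization bounds come from the
designated fitting scope — in cross-validation, the training fold only —
and out-of-scope values are clipped to [0, 1], so test-fold DFI never sees
test-fold statistics.

## Evaluation protocol

Folds are cut at the recording level: within each label class, recording
ids are shuffled (seeded) and dealt round-robin, so per-fold class counts
differ by at most one and no recording is ever split across folds. The
scaler (per-feature min/max) and the DFI bounds are fit on training-fold
rows only; test rows are scaled with clipping. Classifier settings are
fixed with no tuning: SVM (RBF, C = 1), decision tree (depth 10), random
forest and XGBoost (100 estimators, depth 10), KNN (5 neighbours);
everything else is the library default. Metrics follow the standard
confusion-matrix formulas; 0/0 ratios are defined as 0 with a warning.
Multiclass tasks are macro-averaged one-vs-rest with equal class weight.
Headline numbers are the mean over the test folds; confusion matrices are
summed over folds. For binary tasks the positive class is the
ictal/seizure-like class. A single master seed fans out to the fold plan,
every classifier instance and the permutation checks through a
multiplier–counter scheme, making runs reproducible end to end.
Cross-dataset evaluation is the same machinery without CV: fit scaler and
model on one feature table, score once on the other.

## Exact Shapley attribution

With M = 5 features all 2⁵ coalition values are enumerated, so the
attributions are exact — no sampling and no run-to-run variation. The
coalition value g(S) is interventional: the model is evaluated on the
background table with the features in S overwritten by the instance's
values, and the outputs averaged. Each coalition value is computed once
and cached, which makes the local-accuracy identity
φ₀ + Σφ_j = ŷ hold to floating-point accumulation error (≲ 1e-15 in
practice; the tests assert 1e-9). For probabilistic classifiers the
explained output is the predicted class's probability (configurable to any
class). The background defaults to the training fold subsampled to ≤ 256
rows with a seed; background size is the cost knob, since each instance
needs 2^M model evaluations over the background. Enumeration is refused
above 12 features.

## Synthetic data generator

The generator's role is to emulate the statistical structure the features
are designed to detect, with exact ground truth. Background: Gaussian
noise spectrally shaped to power ∝ 1/f^exponent (default exponent 1,
pink-like, as in resting EEG), blended with a random-phase sinusoid;
the two components are unit-RMS normalized and mixed with amplitude
weights (1 − r, r) where r is the state's *regularity*, then scaled to
15 µV RMS. Events: raised-cosine (Hann) pulses — smooth, single-peaked,
with analytically controlled trough-to-trough width and exactly zero
endpoints, so on a zero background the detector's support, duration,
amplitude and energy equal the logged ground truth bit-for-bit. Event
times are Poisson with non-overlap rejection (2-sample guard gap, bounded
retries); widths and amplitudes are drawn uniformly inside the clinical
bands, and each event's true class is recorded by applying the same
duration–amplitude rules the detector uses.

Default state profiles (fixture parameters, not physiological claims):

| state | spike rate (s⁻¹) | sharp rate (s⁻¹) | regularity | amplitudes (µV) |
|---|---|---|---|---|
| interictal | 0.05 | 0.05 | 0.2 | spike 60–150, sharp 110–190 |
| preictal | 0.5 | 0.75 | 0.4 | spike 60–150, sharp 110–190 |
| ictal | 2.0 | 2.0 | 0.7 | spike 120–200, sharp 150–195 |

Rising rates and rising regularity toward ictal produce the intended
directions — wave energies increase, PE and HFD decrease, preictal
intermediate — and the tests assert these orderings across multiple
master seeds. Two realism choices keep the complexity features from being
unrealistically clean: the realized regularity is jittered per recording
by ±0.35 (truncated to [0, 1]), modelling inter-subject variability, and
the oscillation frequency is drawn per recording from a band (6–11 Hz)
shared by all states, so frequency is a nuisance rather than a label cue.
With these defaults the wave-energy family is the most discriminative
feature family in the three-state study and the full five-feature set
outperforms either family alone, which is the qualitative structure the
method presumes in real epileptic EEG. Seeding uses `SeedSequence`
spawning from one master seed: identical seed, bit-identical dataset.

What the generator does **not** model: true epileptiform morphology
(spike-and-wave complexes, polyspikes), artifacts (EMG, eye blinks,
electrode pops), non-stationary background drift, multichannel structure,
and recording-to-recording hardware variation. Passing tests on this
fixture therefore demonstrate correctness of the pipeline's mechanics and
its statistical protocol — not clinical-grade detection performance on
real recordings.

## Problem sizes and numerical choices

The synthetic classification study uses 50 recordings per state of 23.6 s
at 173.61 Hz (31 windows each, 4650 windows total) under 10-fold
recording-stratified CV — large enough for stable fold metrics while the
whole study (generation, extraction, three ablation rows with XGBoost)
completes in well under a minute on one CPU. Detector closed-loop checks
use eight zero-background recordings (≈ 270 events). Tie-breaks are fixed
throughout (stable ordinal ranking; spike-before-sharp classification;
greedy left-to-right event acceptance; 70 ms owned by the sharp class);
degenerate inputs have defined results (constant signal → HFD 0 with
warning, zero-variance feature → scaler maps to 0 with warning, 0/0
metric → 0 with warning) so batch runs never throw on edge cases.

## Known limitations

- The detector measures duration trough-to-trough on the raw signal; on a
  noisy background the strict-descent walk stops at the first noise
  uptick, shortening measured durations relative to the underlying pulse
  and occasionally relabelling wide transients. This is inherent to
  rule-based transient detection without prior smoothing.
- PE and HFD defaults (m = 3, τ = 1, k_max = 10) are tuned to the
  256-sample window; other window lengths may warrant other settings, and
  all are configurable.
- Feature min–max scaling is sensitive to single extreme training
  windows; clipping bounds the effect on test folds but a robust-quantile
  scaler could be preferable on artifact-heavy data.
- The exact Shapley implementation is intentionally limited to low
  feature counts (≤ 12); it is not a general-purpose SHAP replacement.
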