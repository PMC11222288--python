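# Methods

This note documents the models, conventions and parameter choices behind
`pursuitlock`, in the order data flows through the pipeline. Everything
stated here about behaviour on synthetic data is computed by the test
suite or the example scripts; nothing is quoted from elsewhere.

## Gaze model and the recognition moment

**Velocity.** Gaze is sampled at a nominal 60 Hz as screen-pixel
coordinates. Consecutive-sample displacement is converted to visual
angle through the viewing geometry — physical screen size and viewing
distance are required configuration, defaulting to a 53 cm-wide display
at 60 cm, because a °/s threshold is meaningless in pixels. The angle is
the chord angle `2·atan(d/2D)`; per-sample speed divides by the actual
inter-sample interval, and the first sample inherits the second's speed
so the series matches the trace length. No smoothing is applied by
default; a 3-sample median filter is available by flag.

**I-VT classification.** Speed ≥ 30 °/s → saccade, otherwise
sub-threshold. The boundary (exactly 30 °/s) counts as a saccade; this
convention is arbitrary and documented rather than load-bearing. A
velocity criterion alone cannot distinguish fixation from smooth
pursuit of a slowly drifting target, so the package treats any
*sub-threshold, target-coincident* sample as pursuit.

**Recognition moment.** Scanning in time order from target onset, the
alignment time is the first sample that (a) lies within the annotated
target region dilated by a 1° tolerance, (b) is sub-threshold, and
(c) begins a run of at least `min_dwell_samples` (default 3, ≈ 50 ms)
consecutive such samples. The dwell rule rejects single-sample glances
through the region; setting it to 1 recovers the bare first-coincident
rule. Saccadic samples never align even when coincident. Gaze (60 Hz)
and EEG (1 kHz) share the recording start; the alignment time is snapped
to the nearest EEG sample when epoching.

The trigger baseline simply aligns to the annotated onset time, which is
what hardware event markers provide.

## Preprocessing chain

Fixed order, applied to continuous recordings: (1) baseline correction —
subtract each channel's mean over the first 10 % of samples; (2)
amplitude rejection — epochs whose absolute maximum strictly exceeds
200 μV are dropped (applied after epoching; the strict “>” means a
200.0 μV epoch survives); (3) polyphase resampling to 200 Hz; (4)
zero-phase (forward–backward) windowed-sinc FIR band-pass 0.5–49 Hz,
Hamming window, order chosen for a ≤ 0.5 Hz transition at the low edge
(capped below the signal length for short recordings); (5) artifact
component removal; (6) common-average reference.

The artifact stage is pluggable. The default heuristic estimates FastICA
on a copy band-passed to 2–49 Hz, then removes components that either
correlate strongly (|r| > 0.7) with a frontal-channel reference with
frontal-dominant mixing weights (the blink signature) or concentrate
> 80 % of their power below 3 Hz with frontal topography. Decomposition
failure degrades to pass-through with a warning. An `identity` strategy
is selectable and is what the fast test paths use. These thresholds are
a deliberate, simple stand-in for classifier-based component labelling;
they are validated only on the simulator's blink model.

Note a physical consequence of the common-average reference: on a sparse
montage (the simulator's 8-channel default) it removes the mean of a
parietal-focal ERP across channels and so attenuates the Pz peak by
roughly the montage-average of the scalp gains (~2/3 here). With a dense
59-channel cap the attenuation is much smaller. Recovery tests that
check the injected 3.4 μV amplitude therefore run on raw epochs;
pipeline tests check timing, not absolute amplitude.

**Epochs.** Windows are half-open and relative to the alignment time:
[0, 1) s target, [−4, −3) s nontarget, both from target trials. A
nontarget window that would precede the recording start is omitted
(logged); a target window past the end skips the trial. Target and
nontarget windows must be equally long so epochs stack into one array.

## Signatures

**ERP.** Grand averages are pointwise means ± SD across epochs; the peak
is the maximum positive deflection in a configurable search window
(default 0.2–0.6 s). Method comparison uses the two-sided Wilcoxon
signed-rank test on per-subject peak latencies/amplitudes, exact null
for n ≤ 25, zero differences discarded; identical inputs return p = 1 by
definition (no evidence of shift).

**ERSP.** Morlet decomposition with cycle count
`3 · (f/f_min)^0.5` — three cycles at the lowest frequency, window
shrinking half as fast as a fixed-cycle wavelet would, which is the
common EEG time-frequency convention for a “3-cycle wavelet with 0.5
expansion”; the exponent is configurable. Grid 1.2–20 Hz in 0.1 Hz steps
(189 bins). Power is averaged over epochs and expressed as
`10·log10(P / P_baseline)` per frequency; the default baseline is the
first 20 % of the epoch, and the pre-recognition segment is the
recommended explicit choice. The epoch must be at least one full wavelet
long at the lowest frequency (2.5 s at defaults), so ERSP is computed on
wide epochs (e.g. [−4, 2) s), not the 1-s decoding windows. Two known
systematics: frequencies with negligible true power have meaningless dB
(ratio of near-zeros), and a whole-epoch baseline inherits a small
positive bias from edge-deflated power; the white-noise calibration test
quantifies the residual.

## Decoding

**Features.** Epochs are z-scored per channel per epoch (zero-variance
channels map to zero features), then transformed with a complex Morlet
CWT (PyWavelets `cmor1.5-1.0`) on scales tiling 1–13 Hz at 0.5 Hz
spacing; squared magnitudes are summed across scales at each time
sample. A 1-s epoch at 200 Hz gives 200 features per channel,
concatenated across channels (11,800 at a 59-channel montage). This CWT
implementation is independent of the ERSP path's FFT-convolution
transform, so the two can cross-check each other.

**Channel selection.** Per-feature Fisher score
`J(i) = S_B(i)/S_W(i)` with `S_B = Σ_k (n_k/n)(m̄_k − m̄)²` and
`S_W = (1/n) Σ_k Σ_j (x − m̄_k)²`; an ε = 1e−12 guards zero within-class
variance. Channel score is the mean of its features' scores (max
selectable). Channels are visited in descending score (ties by index)
and kept only if the gate — an SVM with the default hyperparameters,
internal stratified 5-fold CV — strictly improves on the best accuracy
so far; the top-ranked channel is always kept. No explicit redundancy
term is computed: a redundant channel is rejected because it cannot
raise gate accuracy.

**Classifier stack.** Standardize → PCA keeping the smallest component
count reaching 90 % explained variance → *re-standardize the
components* → classifier. The re-standardization is a design choice this
package makes deliberately: a fixed RBF width (γ = 0.05) is only
meaningful relative to a feature scale, and raw wavelet-power magnitudes
put the kernel in its degenerate regime. Classifiers: SVM (RBF,
γ = 0.05, C = 1.0), RLDA implemented in-package — pooled within-class
covariance shrunk toward scaled identity,
`Σ(λ) = (1−λ)Σ̂ + λ(tr Σ̂/d)I` with λ = 0.9, linear discriminant rule
with empirical priors (λ = 0 reproduces plain LDA, tested against an
independent implementation) — and XGBoost (20 estimators, dart booster,
depth 10, η = 0.1). Hyperparameter search is intentionally absent: the
defaults are fixed operating points.

**Cross-validation.** Stratified 6-fold; channel selection,
standardization, PCA and the classifier are all fitted inside each
training fold. Metrics: accuracy, TPR on the target class, FPR on the
nontarget class, fold-wise and mean ± SD.

## Pseudo-online evaluation

Trials are split 80/20, stratified by target presence. The decoder is
trained on gaze-aligned epochs of the training split; each test
recording is preprocessed identically, then scanned with 1-s windows
advanced by 100 ms (exactly 20 samples at 200 Hz), starting 2 s before
the target onset on target trials and spanning the whole recording on
nontarget trials (the grid convention is logged). Each window is
featurized exactly like a training epoch and classified; a command fires
when k consecutive windows output “target”, stamped at the end of the
k-th window, after which the run counter re-arms.

Scoring per threshold k: a *hit* is a command within (onset,
onset + 1.5 s] on a target trial; a *false alarm* is any command on a
nontarget trial or a command at or before onset on a target trial.
Commands later than the hit window are ignored by default (logged); a
strict mode counts them as false alarms. HR = hits / target trials;
FAR = trials with ≥ 1 false alarm / all trials;
SA = (1 − FAR + HR)/2, an identity that holds exactly for every report.

**A structural observation.** With search delays up to 3 s, a hit is
impossible whenever delay + detection latency exceeds the 1.5-s hit
window — the neural response has not happened yet when the window
closes. Likewise, scanning a whole 20-s nontarget recording offers ~190
windows of false-alarm opportunity, so trial-level FAR is extremely
sensitive to per-window specificity. High SA therefore requires both
fast target discovery and a per-window false-positive rate well below
1 %; the high-SA regime in the tests and examples uses short delays
(0.3–0.8 s) and clean EEG, which is the regime in which high published
hit rates with a 1.5-s hit window are internally consistent. Raising k
suppresses false alarms (consecutive misfires are rare) at the cost of
detection latency, which is why HR and FAR both fall monotonically
with k.

## Synthetic-trial generator

The simulator produces what the method assumes, with ground truth —
nothing more:

* **Trials.** 20-s videos; target present with probability 0.5 (exact
  count `round(n·p)` at dataset level); onset uniform in 5–12 s;
  search delay uniform in 0.3–3 s, truncated so the recognition moment
  plus the 1-s target window fits in the video; the recognition moment
  is snapped to the 60 Hz gaze grid.
* **Gaze.** Search = fixations of 0.2–0.4 s at random points ≥ 300 px
  apart (inter-fixation jumps are genuine saccades, hundreds of °/s),
  kept clear of the dilated target region after onset so coincidence
  cannot happen before recognition by construction; pursuit = target
  centre (drifting at 30 px/s with mirror reflection at the margins)
  plus isotropic jitter (σ = 3 px; 0 in noiseless tests). Jitter-induced
  speeds stay far below 30 °/s except vanishingly rare excursions.
* **EEG.** Per channel: 1/f-shaped Gaussian noise (exponent 1, RMS
  4 μV) + alpha 10 Hz (4 μV), theta 5.5 Hz (2.5 μV), delta 2.5 Hz
  (2 μV) oscillations with random phases. On target trials the
  alpha/theta envelope ramps down to ×0.4 from 0.7 s after recognition,
  and the delta envelope ramps up ×2 from recognition for 1.5 s. The ERP
  template — an asymmetric raised-cosine bump, exactly 3.4 μV at 300 ms,
  zero at both ends, 0.8 s long — is added at the recognition moment
  with a parietal-maximal scalp weighting (Pz = 1, falling with 10-20
  distance, floor 0.25). Optional blink artifacts: frontal-weighted
  120 μV transients at 0.2 Hz.
* **Determinism.** Every trial is a pure function of
  `(params, trial_seed)`; datasets record per-trial seeds in a manifest
  and reproduce bit-identically (floating-point identical on one
  platform/BLAS; across platforms, to numerical round-off).

The SNR defaults were set so that the default condition is a *clean,
decodable* recording: 6-fold SVM accuracy ≥ 0.90 on a few hundred
gaze-aligned epochs, which is the regime the decoding stage is specified
against. What the simulator does **not** model: real ocular
biomechanics (no main-sequence velocity profiles, no overshoot),
blinks' pupil-signal interaction, non-stationary background EEG,
inter-subject variability, electrode noise, or any rendering of actual
video frames. Passing recovery tests therefore demonstrates internal
consistency of the pipeline — alignment, spectral estimation and
decoding recover what was injected — not performance on real
recordings.

## Default montage and formats

The simulator's default montage is eight 10-20 sites
(Fz, Cz, C3, C4, Pz, P3, P4, Oz); channel count is configuration, not
contract, and the feature-dimension law is checked at 59 channels.
Native EEG storage is a `.npz` array plus a JSON sidecar (labels,
sampling rate, events, reference); EDF(+) files are read through `mne`
(annotations become events; amplitudes are converted to μV). Gaze files
are `time,x,y` CSV; annotations are JSON with an explicit time-varying
target region. Times are seconds (float64) from recording start;
intervals are half-open.
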