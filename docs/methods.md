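# Methods

This note records the scientific and numerical choices behind the
package: what the simulator emulates, how the detectors and the
classifier are defined, which defaults were open design decisions, and
what a passing test does and does not establish.

## 1. Signal model and the synthetic generator

A reading recording is modelled as two channels sampled at 100 Hz
(configurable; must exceed twice the 10 Hz analysis band edge).

**Horizontal channel.** Reading is a per-word loop: a fixation plateau
whose duration is drawn from a Gaussian truncated below at 80 ms, then a
30 ms linear saccade ramp one word-step to the right.  With probability
`regression_prob` — one Bernoulli per word, drawn in word order from a
dedicated random stream so an external oracle can replay the schedule —
a regression is inserted after the word's fixation: a fast leftward step
of 1.5 word-steps, a re-reading fixation of 0.7× the word's fixation,
and a compensating rightward return.  The 1.5-step amplitude reflects
that regressive saccades typically return more than a single word; it
also keeps regressions well separated from both the detector's minimum
drop (0.6 steps) and the sweep-exclusion bound.  Each line of 8 words
ends with an 80 ms sweep back to the left margin, and the recording ends
with a final return sweep placed after the end marker (a hard stop would
create an unphysical step edge).

**Vertical channel.** Blinks arrive as a renewal process — an 0.8 s
physiological refractory gap plus an exponential waiting time whose mean
keeps the effective rate near `blink_rate` per minute.  Each blink is a
biphasic pulse: a raised-cosine positive lobe of half-width
`blink_rise_time` (default 150 ms, so the up-crossing→crest latency of
any sub-peak threshold falls inside the detector's 50–400 ms window) and
a small (−20%) undershoot.

Both channels receive white Gaussian noise (default sd = 5% of a
word-step) and an optional 50 Hz mains component.  Every injected event
time and the reading duration are stored as ground truth, in seconds
from the start marker.

**Group presets.** TDC: 250 ms mean fixation, regression probability
0.05, 12 blinks/min.  Dyslexia: 400 ms, 0.20, 20/min.  The *directions*
(dyslexia slower, more regressions, more blinks — and consequently
longer recordings with higher energy) mirror the group differences
reported in the reading literature; the magnitudes are synthetic
choices made for clear separability at desk scale and should not be
read as clinical estimates.  Cohorts add per-subject log-normal jitter
(10% sd) on fixation duration, blink rate and regression probability.

**What the generator does not emulate:** corneo-retinal dipole physics
or gaze position in degrees; cross-talk of blinks into the horizontal
channel; drift, electrode pops, or non-stationary noise; within-subject
learning effects across texts.  Green detector tests therefore establish
correctness of the detection logic under the stated morphology, not
field performance on clinical recordings.

## 2. Preprocessing

4th-order Butterworth band-pass, 0.1–10 Hz, applied forward–backward
(zero phase) so event latencies are undistorted; this squares the
magnitude response, giving ≫40 dB at 50 Hz.  Blink detection
additionally uses a 50 Hz IIR notch (Q = 30; narrow enough to leave the
pass-band < 2% changed) and median baseline correction.  At a 100 Hz
sampling rate, 50 Hz sits exactly at Nyquist, so the notch stage is
skipped with a warning; it runs only for sampling rates above 100 Hz.
Framing for scalograms tiles half-open 1000-sample windows and drops
the remainder — padding would fabricate signal content in the images.

## 3. Event detectors

**Blinks.** Per-signal threshold `T = median + k·MAD` (normal-consistent
MAD, k = 4): robust scale resists the blinks' own outliers, and the rule
adapts to each signal's noise floor.  Contiguous supra-threshold
excursions become candidate events; the crest is the excursion maximum
and the event is accepted iff the up-crossing→crest latency lies in
[50 ms, 400 ms] (the wider literature window of 100–800 ms is available
through `BlinkConfig`).

**Regressions.** First difference over a 50 ms window; candidates are
drops of at least `0.6 ×` the median word-step (estimated from the
positive differences of the same signal, so filter attenuation cancels)
but smaller than `0.5 ×` the signal range, which excludes line-return
sweeps.  Because zero-phase filtering smears a sweep, its shoulders can
fall between those two bounds; sweeps are therefore *located* — with the
50 ms difference and a 3× longer one that captures the full sweep
magnitude — and all candidates within 150 ms of a sweep centre are
suppressed.  Candidate runs collapse onto their most negative step and
consecutive events must be ≥ 150 ms apart.  `features()` extends the
detection window 0.3 s past the end marker so the post-reading return
sweep is recognised as a sweep rather than leaking edge artifacts, and
then keeps only events inside the marked interval.

**Features and statistics.** Blink rate = blinks per minute of reading
time; regression rate = regressions per word; energy = `Σ x[n]²` of the
horizontal channel over the marked interval (unit sample spacing, so
units are a.u.²·samples).  Group comparisons use Welch's two-sample
t-test per grade and feature, under two units of analysis — per-subject
means (conservative; recordings of one subject are not independent) and
pooled per-recording — both reported and labelled.  Stars: `*` p < 0.05,
`****` p < 0.0001.

## 4. Scalograms

Analytic Morlet wavelet (ω₀ = 6), 12 voices per octave over 0.1–10 Hz,
computed in the Fourier domain with L2 normalisation; the frequency
attached to scale *a* is the centre frequency ω₀/(2πa).  The energy
scalogram is |W(a,b)|², non-negative and 4×-homogeneous under 2×
amplitude scaling.  Images are rendered directly from the power matrix:
log₁₀ power (with a floor at 10⁻¹² of the frame's maximum, keeping the
map scale-invariant), per-image min–max normalisation, a 256-entry
jet-like lookup table, bilinear resize to the model's input size
(28×28; 227×227 supported for AlexNet-shaped plug-ins).  A constant
scalogram maps to the uniform mid-colour.  Rendering is a pure function
of the frame, so a frame and any positive rescaling of it produce
identical pixels — classification results are consequently
normalisation-, not amplitude-, driven.

## 5. The classifier

Four convolution blocks (4×4 kernels, stride 1, 'same' padding — 1 + 2
asymmetric padding for the even kernel — with 16/32/64/64 filters),
each followed by batch normalisation and ReLU.  The published layer
table's pooling row ("2×2, stride 2": 28→7) is arithmetically
impossible; the implementation uses a 4×4 stride-4 pool after block 1
and a 2×2 stride-2 pool (floor: 7→3) after block 2, which reproduces
every printed activation shape (28×28×16, 7×7×16, 7×7×32, 3×3×32,
3×3×64) and the fully connected input of 576 = 3·3·64, leaving all
learnable counts unchanged (784, 32, 8224, 64, 32 832, 128, 65 600,
128, 1154; ~109k total).  Dropout 0.5 precedes the 2-unit FC layer and
softmax.

Training (schedule unspecified in the source material, so a design
default): Adam, learning rate 10⁻³, batch 64, 20 epochs, cross-entropy;
inputs zero-centred by the training-set mean image and scaled by 1/255.
All randomness (He-initialised weights, dropout, shuffling) derives
from `random_state`.  Outputs are reproducible up to float32
accumulation order under multithreaded BLAS; bit-exactness requires a
single-threaded BLAS.  For the small image sets used in tests the batch
size is lowered to 16 and epochs raised so each fold still takes enough
optimisation steps.

**Evaluation.** Stratified k-fold (default k = 5).  `split_unit="frame"`
mirrors the common frame-level protocol but allows frames of one
recording on both sides of a split — an optimistic-leakage caveat;
`"recording"`/`"subject"` give group-disjoint folds and are recommended
for generalisation claims.  Fold metrics aggregate as arithmetic mean ±
sample standard deviation (ddof = 1), and per-fold confusion matrices
sum element-wise into the overlapped matrix.  Zero-denominator metrics
are reported as NaN with a flag, never silently 0.

## 6. Numerical and degenerate-input choices

- Filters reject signals shorter than the forward–backward warm-up.
- A flat signal has MAD 0; the blink threshold falls back to the
  standard deviation (and an all-zero signal yields no events).
- `aggregate_folds` of a singleton returns std 0 by convention, flagged.
- Tie-breaks: max-pooling backward routes gradient to the argmax
  (first maximum on ties); regression candidate runs keep the earliest
  event when separation conflicts.
- Simulator seeds spawn four independent streams (fixation, regression,
  blink, noise) in a fixed, documented order.

## 7. Known limitations

- The synthetic world is deliberately well-separated; classification
  accuracies near 100% on the horizontal channel say the pipeline can
  recover constructed group structure, not that clinical accuracy of
  that magnitude should be expected.
- Frame-level cross-validation inflates accuracy relative to
  subject-disjoint splits; both are provided.
- The wavelet family and colormap of the original MATLAB workflow are
  not published; Morlet + jet is a documented, configurable stand-in,
  so images are not pixel-comparable to any external figure.
- EDF export is not provided (no EDF library in the supported
  environment); the on-disk format is CSV plus a JSON sidecar.
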