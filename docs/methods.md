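# Methods

## Problem and pipeline

A collar-mounted noise sensor reports, 138 times per second, the
peak-to-peak range of its microphone voltage after 10-bit quantization
over 0–5 V (one code = 5/1023 V ≈ 4.888 mV). A vocalization event is
therefore a short univariate sequence of volts — its intensity envelope —
and the classification task is to assign one of four classes (barking,
growling, howling, whining) to each event. The pipeline is: sensor
simulation (from audio) or direct intensity input → per-event 0–1
normalization → cubic-convolution length augmentation (default ×3) →
zero-padding to a fixed width → LSTM-FCN → softmax. An energy model
quantifies why the intensity representation is worth this trouble.

## Sensor simulation

Audio amplitudes in [−1, 1] map affinely onto 0–5 V with the PCM zero at
mid-scale, 2.5 V (electret bias convention; peak-to-peak is bias-invariant
so this choice is unobservable in outputs). Codes are rounded half-up.
Frame *i* of a clip sampled at `sr` Hz covers samples
`[floor(i·sr/138), floor((i+1)·sr/138))`; the trailing partial frame is
discarded, so output length is `floor(n·138/sr)` regardless of `sr`.
The per-frame output `(max code − min code)·LSB` is by construction a
nonnegative integer multiple of one LSB. Quantization granularity means
scaling a waveform's amplitude down can raise an individual reading by at
most one code (rounding-phase effect); the amplitude-monotonicity
property is therefore stated, and tested, to within one LSB.

dB conversion uses `20·log10(max(v, LSB)/v_ref)` with `v_ref` defaulting
to one LSB, so the quietest nonzero reading maps to 0 dB; the reference
is configurable since axis conventions for intensity-level plots vary.

### Sensing-fidelity (RMSE) analysis

To ask whether the cheap sensor preserves class identity, events from a
reference intensity path and from the simulated sensor path are resampled
to a common length (endpoint-aligned cubic resampling — both versions of
an event span the same duration), converted to dB, and compared with RMSE.
The class-pair matrix averages RMSE over matched event ids on the
diagonal (same recordings through both paths) and over the cross product
off the diagonal, where no natural pairing exists. The qualitative target
is diagonal dominance: same-class error below the off-diagonal row mean.
Whether this comparison is better made in dB or volts is a convention;
dB is the default, volts a switch.

## Preprocessing

* **0–1 normalization** `(x − min x)/(max x − min x)` per event, applied
  before interpolation. A constant event (silent clip) has a degenerate
  range and is mapped to zeros with a warning rather than an error, so
  batch pipelines survive.
* **Cubic-convolution resizing** uses the Keys piecewise-cubic kernel
  with sharpness `a = −0.5`, four taps per output sample, replicated
  boundaries (replication avoids inventing out-of-range energy). Two
  grid conventions are used deliberately: *length augmentation*
  (`resize_cubic`, output `round(n·factor)`) pins the start of the grid
  (`x = j/factor`) so integer-aligned positions reproduce input samples
  to 1e−9 and the envelope is stretched, not re-anchored;
  *length alignment* (`resize_to_length`) maps endpoints onto endpoints,
  the right convention when two sequences represent the same time span.
  When shrinking, the kernel is stretched by the inverse scale
  (anti-aliasing) and weights renormalized. The kernel reproduces
  constants and straight lines exactly away from the replicated edges.
* **Padding** with zeros on the right, after interpolation, to width
  `round(max_dim · factor)` (default `round(647·3) = 1941`); zero equals
  the normalized floor. Events longer than `max_dim` raise an error
  rather than being truncated.

## Synthetic data

No recordings are redistributable, so the generator emulates the
statistical structure the pipeline consumes — not bioacoustic fidelity
(no formants or harmonic stacks).

* **Lengths** (samples at 138 Hz) are log-normal, moment-matched to each
  class's published median (`μ = ln median`) and mean
  (`σ = sqrt(2·ln(mean/median))`), then clipped to the published
  min/max: barking 5–47 (mean 19.24, median 19), growling 16–405
  (59.59, 56), howling 51–646 (188.60, 161), whining 5–198 (27.97, 19).
  A log-normal is used because mean ≫ median for three of the four
  classes rules out symmetric laws. Empirical means at n = 300 fall
  within a few percent of the targets.
* **Envelopes** follow the qualitative class descriptions: barking —
  fast rise then exponential decay (peak in the first sixth); growling —
  sustained band with strong multiplicative "jagged" modulation
  (sinusoid at 0.2–0.5× the frame rate plus noise) and soft onset/offset;
  howling — slow monotone-trend decay from a high start; whining — low
  amplitude, 2–3 Gaussian humps, strong jaggedness. Peak amplitudes
  track the published example rows qualitatively (barking loudest ≈4.8 V,
  whining quietest ≈2.4 V); exact published voltage summary values are
  not targeted because their scale exceeds the stated 0–5 V ADC range
  (unit ambiguity in the source).
* **Paired audio** renders the same envelope as an amplitude-modulated
  tone-plus-noise carrier with instantaneous double-sided amplitude
  `envelope/5`, so a full-swing carrier recovers approximately the same
  intensity after sensing. Class-specific carrier frequencies (400–1200
  Hz) stay below Nyquist for any supported rate and leave several cycles
  per frame.

What passing tests on this data do **not** show: robustness to ambient
noise, sensor frequency response, dog-to-dog variability, or the actual
accuracy obtainable on real recordings. They do show that the pipeline
recovers class structure that is present in intensity envelopes, and
that every stage composes correctly.

## Classifier

Dual-branch LSTM-FCN. FCN branch: three 1-D 'same' convolutions
(default 128/256/128 filters, kernels 8/5/3), each followed by batch
normalization (momentum 0.9, ε = 1e−5) and ReLU, then global average
pooling. LSTM branch: the dimension shuffle presents the length-L series
as a single time step of L features; with zero initial state the cell
reduces to `c = i⊙g`, `h = o⊙tanh(c)` (the forget gate is present but
inert), 8 units, dropout 0.8 after. Concatenated features feed a dense
softmax. Training: Adam (lr 1e−3, β = 0.9/0.999), cross-entropy,
batch 128. Kernel sizes, LSTM width, dropout and optimizer follow the
standard LSTM-FCN recipe; filter counts, batch size and the 4-class
softmax are the published configuration. Arg-max ties break toward the
lowest class index. No early stopping or validation split beyond the
70/30 stratified split. A NaN loss aborts with a diagnostic.

The network is implemented directly in NumPy (single precision): the
convolution is computed as one BLAS matrix product per kernel tap, and
all gradients are hand-derived and verified against central finite
differences in the test suite. Training is seeded and bit-reproducible
across runs on the same platform.

### Desk-scale sizing

The published configuration (1200 events, input width 1941, 128/256/128
filters, 2000 epochs) is available through the config objects, but the
package's default experiment sizing is chosen for a single CPU:
75 events per class (300 total), filters (16, 32, 16), 60 epochs,
interpolation factor 3, model width set by the longest event in the
dataset. Under these conditions the classifier reaches held-out accuracy
≈0.86 at factor 3 (seed 17), and factor 3 versus factor 1 accuracies are
statistically indistinguishable when averaged over seeds — on this
synthetic data the envelope information survives at native length, so
interpolation neither helps nor hurts, unlike on the original recordings
where it lifted accuracy from 74% to 84%. The epoch default in
`LSTMFCNConfig` is 200 (a compromise between the published 2000 and the
60 used in the bundled experiments).

### Negative control

The permuted-label control shuffles the labels of the **whole** dataset
(train and test) before splitting, making every label independent of its
sequence; held-out accuracy then sits at the 0.25 chance level with
binomial variation. Permuting training labels only is not used as a
control: a model that clusters the four envelope families aligns each
cluster with an arbitrary permuted label, and whether those alignments
match the true labels is decided by essentially four coin flips —
chance-level in expectation but with cluster-scale variance.

## Energy model

Per second of sensing: `E_total = E_sense + (data KB / link KB/s)·E_radio`,
battery life `= capacity_mAh · 3.6 · V / E_total / 3600` hours. Device
constants are the published per-second joule figures (sound sensor 0.9 J,
66.4 KB/s; noise sensor 0.1 J, 0.9 KB/s; Wi-Fi radio 0.5 J) rather than
V×I recomputation — the two disagree for the radio (3.3 V × 170 mA =
0.561 W vs 0.5 J/s) and the published table is built from the joule
figures; `volts_times_amps()` exposes the cross-check. Printed-table
conventions, chosen to match every published cell: transmission energy is
**ceiled** to 3 decimals (plain rounding would print 0.000 for the noise
sensor at 1200 KB/s where the table shows 0.001), totals are sensing plus
the ceiled transmission, battery hours are floored to one decimal. The
sound-sensor cell at 1200 KB/s computes to 2.15 h where the table prints
2.2 — the one inconsistency, matched only within 0.1 h. The headline
"about 10×" efficiency ratio is the ratio of displayed hours
(19.6/1.9 ≈ 10.3); the unrounded ratio at 300 KB/s is ≈9.9. KB means
kilobyte as printed (no KiB conversion); radio duty-cycling is not
modelled (the additive per-second model as published).

## Known limitations

* The generator's class separability is by construction; accuracy
  numbers on it do not transfer to real recordings.
* Dataset-level determinism holds for fixed NumPy version/platform;
  BLAS vendor differences could change float32 training trajectories in
  principle, though all checks here bound accuracies rather than assert
  exact trajectories.
* The energy model treats sensing and transmission as additive averages;
  no protocol-level radio behavior (backoff, retransmission).
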