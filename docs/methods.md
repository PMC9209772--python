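# Methods

This note records the modeling choices behind `semgnet`: what each stage
assumes, which parameters matter, what the synthetic-data generator does and
does not emulate, and where the design was genuinely open.

## Signal model and preprocessing

Surface EMG from a forearm cuff is treated as band-limited stochastic
muscle activity (energy concentrated in roughly 10–200 Hz, bandwidth below
500 Hz at fs = 1000 Hz) contaminated by 50 Hz power-line interference,
sub-20 Hz baseline drift/motion artifact, and broadband sensor noise.

**Notch.** An ideal trap filter (unit gain everywhere, a null exactly at the
line frequency) is unrealizable, so the package uses a second-order IIR
notch (`scipy.signal.iirnotch`) with quality factor Q = 30, i.e. a ≈1.7 Hz
−3 dB stop band at 50 Hz — narrow enough to spare the neighboring EMG band.
The realized response has its global magnitude minimum at 50 Hz (verified on
a 0.1 Hz grid) and ≥99% power removal of a 50 Hz tone while a 150 Hz tone
loses <5%.

**High-pass.** 3rd-order Butterworth, cutoff 20 Hz, passband-edge parameter
ε = 1, giving the classic −3.01 dB cutoff gain and 6N = 18 dB/octave
deep-stopband slope. Two realizations:

* *Causal IIR* (default): bilinear transform with prewarping — suitable for
  streaming, exact at the cutoff, correct 18 dB/octave roll-off. Bilinear
  frequency warping bends the realized magnitude relative to the analog
  closed form by up to a few percent in the 5–16 Hz transition region at
  this sampling rate; no causal rational filter can track the analog
  magnitude pointwise there.
* *Exact-magnitude FFT* (offline): the signal's rFFT is multiplied by the
  closed-form magnitude `1/√(1+ε²(Ωc/Ω)^{2N})` directly. The measured
  response reproduces the closed form to numerical precision (<0.1%
  everywhere on 1–400 Hz), is zero-phase, and — because the magnitude is
  applied once, not squared as in forward–backward filtering — keeps the
  18 dB/octave slope.

The fidelity test therefore checks the closed-form match on the exact
realization and the slope/cutoff values on the causal IIR.

Filtering order is notch → high-pass (both linear, so the order is
cosmetic); rectification (|x|) is applied only when building amplitude
features, not in the network's raw-window input path. Per-channel
standardization uses training-set mean/std exclusively; statistics are
persisted to JSON for inference. Decision windows default to 200 ms with a
100 ms step: window plus processing fits comfortably inside a sub-300 ms
real-time decision budget at 1 kHz; both are configurable.

## Redundant-channel pruning

The pruning statistic operationalizes "variance of the signal values of
different actions against a resting benchmark" as: per channel, the variance
across gesture classes of (mean class RMS − mean rest RMS). RMS is the
standard sEMG activation level (and is invariant to rectification). Low
cross-action variance ⇒ the electrode does not modulate with gestures ⇒
redundant. Channels are binned into n_levels = 8 quantile grades by
ascending score; the redundancy weight is the reversed rank code
(n_levels − grade + 1), so weight correlates positively with redundancy and
equal scores always share a grade. The grading is repeated over k = 8
stratified held-in folds (seeded shuffle) and the per-channel weights are
averaged; the n_remove = 10 highest-weight channels are removed, ties
resolved toward the lower channel id. All of score → grade → weight →
aggregate is deterministic given (data, seed, k).

The exact statistic, the grade-to-weight coding and the fold-aggregation
rule were open choices; the ones above are the package's interpretation and
are validated behaviorally: on 16-channel synthetic recordings with a
planted non-modulating subset, the procedure recovers exactly that subset in
20/20 seeds at the generator's default SNR (noise floor 0.05 vs activation
gains 0.5–2.0).

## Window features

IEMG and VAR are computed literally (`Σ|x_i|`, `(1/(N−1))Σx_i²` — the
second moment without mean removal; filtered sEMG is near zero-mean, and
the printed form is kept deliberately). Spectral features use a one-sided
rectangular-window periodogram without detrending: MDF is the lowest bin at
which the inclusive cumulative power reaches half the total (ties resolve to
the lower bin), making it amplitude-invariant; FR is low-band power over
high-band power with inclusive band sums. Band edges default to
LLC/LHC = 20/45 Hz and HLC/HHC = 95/450 Hz — a conventional low/high split
inside the sEMG energy band — and are fully configurable
(`fr_low_over_high` names the implemented orientation). A zero high band is
reported as an error, never returned as infinity.

## 1-D CBAM

Channel attention pools the T×C feature map over time (average and max),
passes both pooled C-vectors through a shared two-layer bottleneck
perceptron (hidden width C/r, rectifier after the first layer, biases off by
default — the hidden nonlinearity and bias policy were unspecified open
choices), sums and squashes: values strictly in (0,1). Temporal attention
pools over feature channels, stacks [avg; max] as a 2-channel sequence and
convolves with a fixed length-3 kernel (zero same-padding) before the
sigmoid. Composition is channel-then-temporal. One block adds exactly
2C²/r + 7 parameters (+C/r + C if MLP biases are enabled). The default
compression rate is r = 8 and must divide C.

The trainable layer and a pure-numpy functional form are cross-checked
against a scalar-loop reference to <1e−6 in the tests, along with the
time/channel permutation invariances and the attenuation property
|F″| ≤ |F|.

## Network, training and ablations

Each input stream (one retained sEMG electrode, or the 3-axis ACC block) is
an independent branch: Conv1D blocks (default 32 then 64 channels, kernel 3,
stride 1, same padding) each followed by batch norm, ReLU, temporal max-pool
(factor 5) and CBAM; a GRU (hidden 64) then reads the pooled, attended
sequence and its last hidden state is the stream vector. The pooling factor
is a desk-scale choice: it shortens the recurrent sequence (200-sample
windows → 8 GRU steps) so the bundled numpy training backend stays fast;
with the GRU disabled the stream vector is instead the global time-average
of the conv features (the global-average-pooling path). Stream vectors are
concatenated, passed through a dropout (p = 0.5) fully-connected layer and a
final softmax layer of size M; argmax ties resolve to the lowest class
index. Layer sizes are all configuration, not architecture constants.

Training is Adam (lr 1e−3, batch 64) on softmax cross-entropy. All
randomness (weight init, batch order, dropout masks) derives from explicit
seeds: identical (config, data, seeds) reproduce final weights
bit-for-bit. The autodiff engine (`semgnet._autodiff`) is a minimal tape
with analytic gradients for every op used; each op is finite-difference
checked in the test suite.

The five ablation topologies — bare multi-stream convolution, +BN, +BN+GRU,
+BN+CBAM, +BN+CBAM+GRU — are generated from one config switchboard, so
their parameter sets differ only in the stated components (asserted
structurally). On the synthetic benchmark the directional property that the
full topology is at least as accurate as the bare one holds in the
data-scarce regime (seed-averaged); in the data-rich easy regime all five
variants sit near ceiling and the ordering between middle variants is not
resolved at desk scale — distinguishing them reliably requires real
recordings at full scale, which is outside this package's scope.

## Synthetic data: what it does and does not emulate

The generator produces, per channel, unit-variance Gaussian noise band-pass
filtered to 10–200 Hz (4th-order Butterworth), multiplied by a trapezoidal
activation envelope (0.5 s rise/fall) scaled by a per-class × per-channel
gain matrix, plus a broadband noise floor (0.05), a 50 Hz sinusoid (amp 0.5,
random phase per channel) and sub-5 Hz low-pass-filtered drift (amp 0.3).
Rest windows (gesture 0) interleave the actions and are annotated as events.
ACC axes emit class-specific raised-cosine pulses plus sensor noise. The
generator is a pure function of its spec, seed included.

Default spec parameters mirror the target acquisition protocol: 16
channels, 1000 Hz, 52 classes, 15 repetitions, 10 s actions; the planted
redundant subset defaults to channels {2,3,4,5,6,10,11,12,13,14}. Two
scaled presets exist for fast runs: `easy` (5 classes, 6 channels, 2 s
actions, 9 repetitions, nearly disjoint activation patterns) and
`planted_redundancy` (16 channels, 6 classes, 1 s actions, 8 repetitions).
The rest interval defaults to 3 s — a realistic between-trial pause; the
protocol-level minutes-long breaks between action blocks are irrelevant to
the algorithms and not emulated.

Not emulated: motor-unit action-potential structure, muscle fatigue
(spectral compression over time), electrode lift/shift artifacts,
inter-subject variability, and realistic cross-channel correlation (an
amplitude matrix row induces correlation in level only; the noise processes
are independent per channel). Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave as designed under the
assumed signal model — not that the reported synthetic accuracies transfer
to recorded data.

## Numerical and scale choices

* Everything runs in float64; attention sigmoids are strictly inside (0,1)
  analytically, but saturate to exactly 0/1 in float64 for |pre-activation|
  ≳ 37 — tests therefore probe strictness at moderate magnitudes.
* Max reductions route gradients to the first maximum on exact ties.
* Quantile grade edges use linear interpolation; scores equal to an edge
  fall in the lower grade.
* Zero-variance channels normalize with a unit divisor and a warning.
* Test-suite problem sizes are deliberately desk-scale: the end-to-end
  accuracy check trains the default small model for 3 epochs on ≈760
  windows; the ablation checks use a 1-block variant (8 conv channels, GRU
  16) with 150–300 training windows over 5 seeds; redundancy recovery uses
  twenty 72.5 s 16-channel recordings. Full-protocol sizes (52 classes × 15
  × 10 s) are supported by the same code paths but are not exercised in CI.

## Known limitations

* The causal high-pass deviates from the analog magnitude near the cutoff
  (bilinear warping); use the exact FFT realization when offline magnitude
  fidelity matters.
* Checkpoints store weights by parameter name; loading requires a config
  that reconstructs the identical topology.
* The CLI's `feature_images` input mode computes sub-window feature
  sequences per decision window; its accelerometer branch still consumes
  raw windows, so mixed-mode pooling factors must be chosen compatibly.
* No GPU or multi-core execution; the training backend is intentionally
  small and single-threaded beyond BLAS.
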