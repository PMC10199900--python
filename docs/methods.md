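# Methods

This note documents the models behind `porecall`, the defaults and the
reasoning for the choices that were genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Generative signal models

Each analyte measured on a given device is described by a blockade
population and a dwell-time model.

**Blockade.** A one- or two-component Gaussian on either the relative
blockade ΔI/I₀ (dimensionless) or the absolute depth ΔI (nA),
truncated by rejection to (0, 1] in relative units — a molecule cannot
increase the current, and an analyte comparable in size to the pore can
block it almost completely, so values near 1 are physical. The
packaged table (`src/porecall/data/signal_library.tsv`) transcribes the
published population means ± SDs per (analyte, device); the ± values
are treated as population SDs of the generative distribution (they
could also be read as fitted peak widths; the two coincide for Gaussian
populations, and the density stage reports both sample and component
SDs). Two populations are bimodal — histidine, and glycine on one
device — attributed to distinct pore-entry orientations. The component
weights of bimodal populations are not published; they default to
0.5/0.5 (symmetric prior absent better information) and are
configurable per table row.

**Dwell.** The published analyses show dwell times on log-scaled
heatmap axes, mostly above 0.1 ms, but no distribution family. We use
a lognormal with median 0.5 ms and log-SD 0.6: a heavy-tailed, strictly
positive family standard for translocation kinetics. With these
defaults the closed-form CDF puts 0.4% of dwells below the 0.1 ms
analysis cut-off, so the dwell filter retains essentially the whole
population — matching measurements in which most events survive the
cut.

**Charge and bias.** Each analyte carries the sign of its net charge at
the working pH (positive for K and R, negative otherwise). An
electrophoretically driven run requires the trans-side bias to have the
*opposite* sign to the analyte charge; the simulator validates this and
refuses mixed-charge runs, since each polarity drives only one charge
class through the pore.

## Trace simulator

The simulated measurement is: baseline at I₀ (default 3 nA, typical of
sub-nanometre pores at a few hundred mV in 1 M KCl) plus white Gaussian
noise; rectangular blockade events; a causal 2nd-order low-pass Bessel
at 10 kHz standing for the recording electronics; 100 kHz sampling.

- **Arrivals** are Poisson (default 10 events/s, an artifact choice —
  event rates at 2 μM analyte are not published) thinned so events
  never overlap and are separated by ≥ 1 ms of clean baseline; counts
  are therefore slightly sub-Poisson (≈1% at default rates). Requests
  exceeding 50% duty cycle are refused.
- **Event shape** is a rectangle of depth ΔI smoothed only by the
  acquisition filter. The analysis extracts only depth and dwell, so
  richer intra-event structure would be invisible to it; this is also
  the key limitation of the synthetic benchmark (below).
- **Voltage scaling** is ohmic: ΔI(V) = ΔI(V_ref)·|V|/|V_ref| with
  V_ref = 200 mV. The experimental observation is only that blockades
  grow from 200 to 300 mV; the linear rule is the simplest monotone
  choice and only monotonicity is asserted in tests.
- **Noise calibration**: white noise is injected before the filter with
  variance pre-scaled by the filter's noise gain (mean squared
  magnitude response over the band), so the post-filter RMS matches the
  configured target (default 0.01 nA). Flicker noise and slow baseline
  drift are available but off by default.
- The ground-truth table is exhaustive and exact; with noise and
  filtering disabled the trace equals I₀ outside events and I₀ − ΔI
  inside, which the detection oracle tests rely on.

## Event detection

The chain mirrors standard nanopore practice (Transalyzer-style):

1. **Filter**: zero-phase (forward–backward) 2nd-order Butterworth at
   10 kHz. Zero-phase application leaves event boundaries unshifted,
   so dwell times are unbiased; the real-time Bessel of the recording
   electronics is emulated in the simulator instead.
2. **Baseline**: centred 300 ms moving average. The baseline is
   estimated twice: a first pass finds candidate events, a second pass
   excludes them from the average (interpolating across the gaps) so
   deep blockades do not drag the baseline down. Edges use shrinking
   windows.
3. **Noise**: robust σ from the median absolute deviation of the
   baseline residual outside events — insensitive to the few percent of
   samples inside events.
4. **Calling**: an event opens where the current drops below
   baseline − 5σ; its boundaries are the surrounding crossings of
   baseline − 2.5σ. The exact thresholds used in the original analyses
   are not published; 5σ/2.5σ hysteresis is common practice and both
   are configuration parameters. On effectively noiseless input
   (σ·threshold below 1% of baseline) the thresholds fall back to an
   absolute 1% of the baseline current.
5. **Features**: Δt from the boundaries; I₀ local from the masked
   baseline; ΔI as the *trimmed* mean of (baseline − sample) inside the
   event, excluding one filter settle time (default 60 µs, capped at a
   quarter of the event) at each boundary. Both filters smear the
   rectangular edges into the event interior; an untrimmed mean is
   biased shallow by several percent at millisecond dwells, which would
   shift every recovered peak. The trim removes the bias without
   touching the plateau. Indices are 0-based half-open, times in
   seconds, currents in nA.
6. **Dwell filter**: events with Δt < 0.1 ms are excluded; the boundary
   is inclusive (an event of exactly 0.1 ms is kept). A warning is
   emitted when fewer than 300 events remain, the usual minimum for
   population statistics.

Recall and precision on default-noise synthetic runs exceed 0.95
(regression-tested); on noiseless unfiltered traces detection matches
ground truth to ±1 sample with exact depths.

## Density statistics

- **KDE**: Gaussian kernel, Silverman bandwidth by default, mode by
  grid argmax with parabolic refinement; local maxima under 5% of the
  global maximum are suppressed as tail wiggles. The KDE mode is the
  package's "mean peak value". Its sampling error shrinks slowly with
  n (the nonparametric mode rate, n^(−2/7)), so benchmark runs for
  broad populations (SD ≳ 0.04) use 2000–3000 events rather than the
  1000 minimum; the consistency of the estimator over n is itself
  regression-tested.
- **Mixtures**: EM (scikit-learn) with full covariance and 10 random
  restarts, components sorted by mean. Bimodal populations are
  summarised by mixture components rather than KDE modes because a
  broad second component need not produce a second KDE mode. A caution
  from the oracle experiments: for the histidine-like mixture
  (N(0.298, 0.026) + N(0.389, 0.068), equal weights) the narrow lower
  component is identified to ~0.005 at n = 5000, but the broad upper
  component sits on a flat likelihood ridge and its fitted mean can be
  off by ~0.03 until n ≈ 10⁵. Only the lower component is treated as a
  reliable summary at realistic event counts.
- **z-test**: Welch (unequal-variance) two-sample z with two-sided
  normal p-value; the pooled-variance variant is not used since
  population SDs differ between analytes. Type-I error is calibrated
  in simulation (5% ± 1.5% at α = 0.05 over 1000 repeats). No
  multiple-testing correction is applied: the experimental claim is a
  single blanket bound (all pairwise P < 0.0001), not a family of
  marginal decisions.
- **Heatmaps**: 2-D dwell × blockade histograms with optional log-dwell
  binning; counts are conserved.

## Classification

**Encoding.** Each event is resampled by linear interpolation to L
points (default 128) over [start − 0.2Δt, end + 0.2Δt], divided by the
local open-pore current (making the encoding invariant to the absolute
current level) and clipped to [−0.2, 1.2]; the scalar features
(ΔI/I₀, log₁₀ Δt) ride along. The published per-event network is
described only as LSTM → pooling → four fully connected layers →
output; the input encoding here is an artifact decision.

**Bayes baseline.** Class-conditional Gaussian mixtures on the scalar
features (component count 1 or 2 chosen per class by BIC, so bimodal
populations are handled without being told), equal priors, maximum
posterior decision. On scalar-generated synthetic data this baseline
*is* the information ceiling, which makes it the transparent reference
for the sequence model.

**Sequence model.** A numpy implementation of LSTM (single layer,
default hidden width 64) → mean-over-time pooling → concatenation of
the scalar features → four fully connected ReLU layers (64, 32, 16, 8)
→ linear softmax. Training: Adam (lr 10⁻³), batch 64, cross-entropy,
global-norm gradient clipping at 5, ≤ 100 epochs with early stopping on
validation accuracy (patience 10) and restoration of the best weights.
Backpropagation through time is verified against numerical gradients in
the test suite. A fixed seed fixes initialisation and batch order, so
accuracies reproduce exactly on a given platform and to within ±1 point
across platforms. Scalar features are appended after pooling so the
network both consumes the raw current vector and the specified
features.

**Evaluation.** Confusion matrix (true × predicted), per-class
precision/recall/F1 (F1 = 0 when P + R = 0), and average accuracy =
trace/total. Splits are stratified 70/15/15 with a seed.

## What the synthetic benchmarks show — and what they do not

The simulator generates exactly the structure the signal models
describe: per-event depth, dwell, noise. Consequently:

- Recovering the published population peaks through the full pipeline
  validates the *analysis chain* (filtering, baselining, calling,
  feature extraction, density fitting) end to end — bias anywhere in
  the chain would shift the recovered peaks.
- Classifier accuracies on synthetic pairs are bounded by the scalar
  Bayes limit; the sequence model can at best match the baseline here
  (a property-tested invariant), because synthetic waveforms carry no
  intra-event structure beyond depth and dwell. Published accuracies
  for hard pairs (D/E, K/R, F/Y/W, E/Q) depend on waveform structure of
  real events and are *not* reproduced or claimed; the benchmark pairs
  (G/A, S/T) are those whose printed population separations alone
  guarantee the floor.
- Device-to-device variability, electrode drift, clogging, flicker
  noise and multi-level events are not modelled.

## Benchmark problem sizes

The benchmark script simulates per target: 2000 events for the
homopeptide depth peaks (population SD 0.021 nA), 1200 for G/A and R,
3000 for S/T (broad SDs), 2500 for Y/p-Y (tight ±0.005 check), 5000
for the histidine mixture; classifier tasks use 2000 events per class
with a 70/15/15 split. These sizes keep the KDE-mode sampling error
well inside the stated tolerances while matching the scale of real
recordings (≥ 300, typically > 1000 events per measurement).

## Numerical details and degenerate inputs

- Seeds: every stochastic stage takes an explicit seed or generator;
  simulate/detect reruns are bit-identical, classifier reruns
  metric-identical.
- Baseline windows shorter than 10 samples or longer than the trace are
  rejected; a fully masked trace is rejected.
- KDE requires ≥ 30 values, mixture fits ≥ 50, z-tests ≥ 30 per sample;
  smaller inputs raise an insufficient-data error (CLI exit code 3).
- Identical samples give z = 0, p = 1; zero variance in both samples
  with distinct means is an error.
- Mixture components are diagonally regularised (reg_covar), so
  singular fits re-initialise rather than fail.
- Event records cap ΔI at I₀ so relative blockades stay in (0, 1].
- Ties in mode ranking are broken toward the lower location.
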