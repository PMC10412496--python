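# Methods

## Signal model and rationale

Foot-worn gyroscope and accelerometer signals during gait are periodic:
each stride produces a large angular-velocity excursion at mid-swing and
an acceleration impact at heel strike. The detector uses the Euclidean
norm of the 3-axis signal, which is invariant under any fixed sensor
mounting rotation, so the method needs no calibration and tolerates
arbitrary sensor placement on the foot. Everything downstream operates on
this scalar norm.

## Peak enhancement

| stage | operation | parameters (defaults) |
|---|---|---|
| 1 | downsample | polyphase anti-aliased resampling to 40 Hz |
| 2 | detrend + low-pass | least-squares linear detrend; Hamming-windowed-sinc FIR, 120 coefficients, cutoff 3.2 Hz, applied forward and backward (zero phase) |
| 3 | wavelet transform | single-scale CWT, second-derivative-of-Gaussian (gaus2) kernel, scale 15 at 40 Hz |
| 4 | smoothing | Savitzky–Golay, order 1, 11-sample (0.275 s) window |

The 40 Hz analysis rate keeps long recordings tractable while leaving the
sub-4 Hz gait band untouched. The 3.2 Hz cutoff removes impact and sensor
noise but passes stride periodicity. The gaus2 kernel at scale 15
corresponds to a pseudo-frequency of roughly 0.8 Hz, matching stride
rates, and acts as combined smoothing and differentiation; its sign is
oriented so a positive bump in the input produces a positive maximum at
the bump centre. If a different analysis rate is configured, the scale is
rescaled proportionally so the enhanced band stays aligned with stride
frequency.

Choices the published operating point leaves open, resolved here:

* **FIR design** — a Hamming-windowed sinc; any standard window design
  with 120 taps at this cutoff behaves equivalently for this purpose.
* **Detrend** — least-squares linear detrend over the whole series, the
  conventional default.
* **Savitzky–Golay window** — 11 samples (0.275 s), shorter than the
  shortest plausible stride, so "slight smoothing" cannot merge
  neighbouring stride peaks.
* **Edge handling** — symmetric reflection padding for the CWT and the
  filters' defaults elsewhere; resampling is performed around the series
  mean so a constant input is reproduced exactly (the polyphase branches
  of the anti-alias filter are not perfectly DC-balanced).

The whole post-norm chain is linear, so scaling the raw signal scales the
enhanced signal by the same factor; the norm itself is positively
homogeneous.

## Peak selection

Candidate peaks are all strict local maxima of the enhanced signal
(plateaus resolved to their centre sample). No minimum-distance
constraint is applied — the enhancement chain already band-limits the
signal near stride frequency. Three selection schemes:

* **fixed** — amplitude ≥ 100 deg/s (gyroscope) or 0.5 g
  (accelerometer); conservative, unit-bound, high sensitivity.
* **adaptive** — the p-th percentile (default 10) of the amplitude
  distribution of fixed-threshold survivors; by construction never below
  the fixed threshold, and subject-specific.
* **hilbert** — walking periods are pre-selected where the Hilbert
  envelope of the enhanced signal stays at or above the fixed threshold
  for ≥ 1 s, after merging gaps < 3 s (both configurable; the criterion
  for "pre-selected walking periods" is otherwise open and this is the
  simplest construction with the intended behavior). The threshold is the
  p-th percentile (default 1) of peak amplitudes inside those periods.

All comparisons are inclusive (≥), making tie behavior deterministic;
percentiles interpolate linearly between closest ranks (type-7). The
adaptive/hilbert threshold is computed once per recording per foot
(global), not per bout; in the dual-sensor configuration each foot gets
its own threshold, which adapts to asymmetric gait.

## Bout grouping

Events (stride peaks for one sensor; the sorted union of left and right
peaks — step events — for two) are scanned left to right. The duration
threshold TH_d starts at 5 s (single) / 3.5 s (dual). Once a bout holds
two or more events, TH_d becomes

    TH_d = offset + mean(intra-bout event spacing),   capped at the start value,

with offset 3 s (strides) or 1.5 s (steps), recomputed after every
accepted event. The initialisation accommodates slow walking (cadence
around 40 steps/min, i.e. ~3 s strides) and tolerates occasional missed
peaks. The cap enforces the hard maximum inter-peak duration; without it
a 3 s-stride walker would accept gaps over 6 s. A gap ≤ TH_d (inclusive)
extends the bout; otherwise the bout closes and a new one starts.

Bout start/end equal the first/last member event time — no half-stride
padding — which biases detected bouts short by about one stride relative
to instrumented-insole style references; the synthetic-data evaluation
quantifies this (see below). Retention: dual-sensor bouts need ≥ 5 steps;
single-sensor bouts need ≥ 3 same-foot strides, the smallest count
implying at least five steps (the five-step rule has no exact single-foot
analogue). Both minima are configurable.

## Evaluation

Bouts are rasterised to per-sample labels at 40 Hz using half-open
[start, end) intervals, so adjacent bouts tile without double counting.
Confusion rates use the standard definitions

    sensitivity = TP/(TP+FN)   specificity = TN/(TN+FP)
    accuracy = (TP+TN)/total   precision = TP/(TP+FP)

with zero-denominator ratios reported as NaN, never 0. A per-second
majority-vote view (`majority_per_second`) is provided for evaluations
that prefer one label per second. The ROC sweep re-runs the full detector
per percentile over a default grid of 1% plus the multiples of 2.5% up to
50% (a strict 2.5% increment from 1 never reaches 50, so the grid is
configurable).

## Synthetic data

The simulator emulates exactly the features the detector uses, not
biomechanics: per-stride raised-Gaussian mid-swing bumps on the
pre-rotation pitch axis (amplitude 250–500 deg/s, stride duration
0.9–1.4 s with 5% cycle-to-cycle jitter, bump width 0.12 stride),
smaller heel-strike/toe-off ripples on the other axes, gravity plus
heel-strike transients on the accelerometer, white rest noise
(σ = 5 deg/s), and isolated 0.5–2 s oscillatory artifacts
(80–250 deg/s raw, straddling the fixed threshold after enhancement so
the fixed and adaptive methods measurably differ). A random fixed
mounting rotation is always applied, so every end-to-end test also
exercises orientation invariance. Ground-truth bout intervals span half
a stride before the first mid-swing to half a stride after the last.

What passing tests on this data do **not** show: robustness to
pathological waveform shapes (shuffling, festination), soft-tissue and
footwear artifacts, sensor drift or dropped samples, or performance at
the true prevalence of walking in daily life. They do show that the
implementation recovers known bouts, orders the three thresholds
correctly, and degrades monotonically with the percentile.

Problem sizes used by the test suite: the grouping oracle enumerates all
contiguous partitions for 500 random trains of ≤ 12 events; confusion
metrics are checked exhaustively on all 256 four-sample label pairs;
orientation invariance uses 20 random rotations of a 120 s scenario; the
parameter-recovery check runs 20 seeds of 10-minute clean-walk scenarios
(six bouts each) and requires per-sample sensitivity ≥ 0.95 and
specificity ≥ 0.90 for the adaptive method at percentile 10. These
statistics describe synthetic data only and are not field-performance
claims.

## Known limitations

* Bout boundaries are event-delimited, so each bout is short by roughly
  one stride versus a pressure-insole-style reference.
* Very slow gait (> 3 s strides) with a single missed peak splits a bout:
  two consecutive 3 s strides bridged by a missed event produce a 6 s gap,
  above the 5 s cap.
* The Hilbert pre-selection is envelope-based and can bridge densely
  spaced artifacts into one pre-selected period, inflating false
  positives in fidgeting-heavy recordings.
* The accelerometer path shares the gyroscope pipeline with only the
  fixed threshold changed (0.5 g); heel-strike peak enhancement is more
  sensitive to the impact sharpness than the mid-swing path is to bump
  width.
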