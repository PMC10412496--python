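# gaitbouts

Detection of walking bouts from one or two foot-worn inertial sensors
(IMUs), for researchers and clinicians who monitor real-world mobility —
daily-life gait in older adults, neurological populations, rehabilitation
follow-up — from days of unsupervised recordings.

## The algorithm

The detector operates on the Euclidean norm of the 3-axis angular
velocity,

&nbsp;&nbsp;&nbsp;&nbsp;ωN = √(ω²_roll + ω²_pitch + ω²_yaw),

(or the acceleration norm aN), which is invariant to how the sensor is
mounted on the foot, so no sensor-to-segment calibration is required.
Three stages follow:

1. **Peak enhancement** — ωN is downsampled to 40 Hz, detrended and
   low-pass filtered with a zero-phase FIR filter (120 coefficients,
   cutoff ≈ 3.2 Hz), transformed by a single-scale continuous wavelet
   transform (second-derivative-of-Gaussian kernel, scale 15) and lightly
   smoothed (linear Savitzky–Golay). The result, ωN-LPF-CWT, has one
   dominant positive peak per mid-swing (per heel-strike for aN).
2. **Peak selection** — stride/step peaks are chosen by one of three
   amplitude thresholds: *fixed* (TH_fixed = 100 deg/s gyroscope,
   0.5 g accelerometer), *adaptive* (TH_adapt = the 10th percentile of
   the amplitudes of peaks above TH_fixed) or *Hilbert* (TH_hilbert =
   the 1st percentile of peak amplitudes within walking periods
   pre-selected by the Hilbert envelope of ωN-LPF-CWT).
3. **Bout grouping** — consecutive peaks with spacing Δt_i ≤ TH_d belong
   to one walking bout. TH_d is initialised at 5 s (one sensor; 3.5 s for
   the merged bilateral step train) and then adapts to cadence,
   TH_d = 3 + mean stride duration (1.5 + mean step duration for two
   sensors), capped at the initialisation value. Bouts with fewer than
   five steps (three same-foot strides) are discarded as non-locomotion.

An evaluation module rasterises bouts to per-sample binary labels,
computes sensitivity / specificity / accuracy / precision against a
reference, and sweeps the adaptive or Hilbert percentile over 1–50% to
trace ROC curves. A synthetic gait simulator generates recordings with
known bouts, rest noise and movement artifacts so the full pipeline can
be exercised and validated without field data.

## Worked example

```python
from gaitbouts import (SimConfig, ThresholdSpec, simulate_recording,
                       detect_walking_bouts, bouts_to_labels, confusion_metrics)

rec, truth = simulate_recording(SimConfig(seed=7))          # 120 s, 3 bouts
bouts = detect_walking_bouts(rec, ThresholdSpec(method="adaptive"))
print(f"ground truth: {len(truth.bouts)} bouts, {truth.n_strides} strides")
for b in bouts:
    print(f"bout {b.start:6.2f}-{b.end:6.2f} s  ({b.n_events} strides)")
m = confusion_metrics(bouts_to_labels(bouts, rec.duration, 40.0),
                      truth.label_vector(40.0))
print(f"sensitivity={m.sensitivity:.3f} specificity={m.specificity:.3f} "
      f"accuracy={m.accuracy:.3f} precision={m.precision:.3f}")
```

prints

```
ground truth: 3 bouts, 68 strides
bout  12.07- 31.80 s  (16 strides)
bout  45.83- 69.70 s  (23 strides)
bout  85.97-108.35 s  (23 strides)
sensitivity=0.956 specificity=1.000 accuracy=0.975 precision=1.000
```

All three simulated bouts are recovered; the slight sensitivity loss is
the expected edge bias (detected bouts span the first to last gait event,
about half a stride inside the true locomotion period) plus the strides
the 10th-percentile threshold trims.

The same pipeline is scriptable from the shell:

```sh
gaitbouts simulate --seed 7 --duration 120 --out-dir sim
gaitbouts detect --input sim/recording.csv --method adaptive --out-dir det
gaitbouts evaluate --pred det/predicted_labels.csv --ref ref_labels.csv
gaitbouts roc --input sim/recording.csv --ref sim/labels.csv --out roc.csv
```

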