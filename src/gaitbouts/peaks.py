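"""Peak selection on the enhanced signal.

Candidate peaks are all strict local maxima of the enhanced norm. Three
amplitude-thresholding schemes then pick the stride/step-related ones:

* **fixed** — a conservative unit-bound cut (100 deg/s for the gyroscope
  norm, 0.5 g for the accelerometer norm) chosen to pass stride events
  across a wide range of walking speeds.
* **adaptive** — the p-th percentile (default 10) of the amplitude
  distribution of peaks already above the fixed threshold; subject-specific
  and always >= the fixed threshold.
* **hilbert** — candidate walking periods are pre-selected where the
  Hilbert envelope of the enhanced signal stays above the fixed threshold;
  the threshold is then the p-th percentile (default 1) of the peak
  amplitudes inside those periods.

All threshold comparisons are inclusive (>=), and percentiles use linear
interpolation between closest ranks (type-7).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import ValidationError
from .enhancement import EnhancedSignal

__all__ = [
    "PeakSet",
    "ThresholdSpec",
    "detect_candidate_peaks",
    "select_fixed",
    "select_adaptive",
    "hilbert_preselect",
    "select_hilbert",
    "select_peaks",
]


@dataclass(frozen=True)
class PeakSet:
    """Peak times (s, analysis clock) and amplitudes, with provenance."""

    times: np.ndarray
    amplitudes: np.ndarray
    method: str = "candidates"
    threshold_value: float = -np.inf
    source: str = "gyro"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)
        if t.size != a.size:
            raise ValidationError("times and amplitudes must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("peak times must be strictly increasing")
        if self.method not in ("fixed", "adaptive", "hilbert", "candidates"):
            raise ValidationError(f"unknown method {self.method!r}")

    def __len__(self) -> int:
        return self.times.size

    def subset(self, mask: np.ndarray, method: str, threshold: float) -> "PeakSet":
        return PeakSet(
            times=self.times[mask],
            amplitudes=self.amplitudes[mask],
            method=method,
            threshold_value=threshold,
            source=self.source,
        )


@dataclass(frozen=True)
class ThresholdSpec:
    """Configuration of the three peak-selection schemes.

    ``percentile`` applies to the adaptive and hilbert methods; if left
    None it defaults to 10 (adaptive) or 1 (hilbert). The pre-selection
    of walking periods for the hilbert method keeps stretches where the
    envelope exceeds the fixed threshold for at least
    ``hilbert_preselect_min_dur`` seconds, after merging gaps shorter than
    ``hilbert_gap_merge`` seconds.
    """

    method: str = "adaptive"
    fixed_gyro: float = 100.0
    fixed_acc: float = 0.5
    percentile: float | None = None
    hilbert_preselect_min_dur: float = 1.0
    hilbert_gap_merge: float = 3.0

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "adaptive", "hilbert"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.fixed_gyro <= 0 or self.fixed_acc <= 0:
            raise ValidationError("fixed thresholds must be positive")
        if self.percentile is not None and not (0 < self.percentile <= 50):
            raise ValidationError("percentile must lie in (0, 50]")

    def fixed_for(self, source: str) -> float:
        return self.fixed_gyro if source == "gyro" else self.fixed_acc

    def percentile_for(self, method: str | None = None) -> float:
        if self.percentile is not None:
            return self.percentile
        return 1.0 if (method or self.method) == "hilbert" else 10.0

    def with_percentile(self, percentile: float) -> "ThresholdSpec":
        return replace(self, percentile=percentile)


def detect_candidate_peaks(signal: EnhancedSignal) -> PeakSet:
    """All strict local maxima of the enhanced signal.

    A plateau is resolved to its centre sample. No minimum-distance or
    prominence constraint is applied: the enhancement chain already
    band-limits the signal near stride frequency.
    """
    v = signal.values
    if v.size < 3:
        return PeakSet(np.empty(0), np.empty(0), "candidates", -np.inf, signal.source)
    idx, _ = sps.find_peaks(v)
    return PeakSet(
        times=idx / signal.fs,
        amplitudes=v[idx],
        method="candidates",
        threshold_value=-np.inf,
        source=signal.source,
    )


def select_fixed(candidates: PeakSet, spec: ThresholdSpec) -> PeakSet:
    """Keep peaks with amplitude >= the unit-bound fixed threshold."""
    th = spec.fixed_for(candidates.source)
    return candidates.subset(candidates.amplitudes >= th, "fixed", th)


def select_adaptive(candidates: PeakSet, spec: ThresholdSpec) -> PeakSet:
    """Percentile-adaptive threshold on peaks surviving the fixed cut.

    The adaptive threshold is the p-th percentile of the amplitude
    distribution of the fixed-threshold survivors, so it is never below
    the fixed threshold. If nothing survives the fixed cut the result is
    empty with ``threshold_value`` equal to the fixed threshold.
    """
    survivors = select_fixed(candidates, spec)
    if len(survivors) == 0:
        return survivors.subset(
            np.zeros(0, dtype=bool), "adaptive", survivors.threshold_value
        )
    th = float(np.percentile(survivors.amplitudes, spec.percentile_for("adaptive")))
    return survivors.subset(survivors.amplitudes >= th, "adaptive", th)


def hilbert_preselect(
    signal: EnhancedSignal, spec: ThresholdSpec
) -> list[tuple[float, float]]:
    """Pre-select candidate walking periods from the Hilbert envelope.

    Returns half-open (start, end) periods in seconds where the analytic-
    signal magnitude stays >= the source's fixed threshold, after merging
    gaps shorter than ``hilbert_gap_merge`` and dropping periods shorter
    than ``hilbert_preselect_min_dur``.
    """
    env = np.abs(sps.hilbert(signal.values))
    mask = env >= spec.fixed_for(signal.source)
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]  # half-open sample runs
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    max_gap = spec.hilbert_gap_merge * signal.fs
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    min_len = spec.hilbert_preselect_min_dur * signal.fs
    return [
        (s / signal.fs, e / signal.fs) for s, e in merged if e - s >= min_len
    ]


def select_hilbert(
    candidates: PeakSet, signal: EnhancedSignal, spec: ThresholdSpec
) -> PeakSet:
    """Envelope-based selection: restrict to pre-selected periods, then
    threshold at the p-th percentile (default 1) of their peak amplitudes."""
    periods = hilbert_preselect(signal, spec)
    inside = np.zeros(len(candidates), dtype=bool)
    for s, e in periods:
        inside |= (candidates.times >= s) & (candidates.times < e)
    if not inside.any():
        return candidates.subset(inside, "hilbert", np.nan)
    th = float(
        np.percentile(candidates.amplitudes[inside], spec.percentile_for("hilbert"))
    )
    return candidates.subset(
        inside & (candidates.amplitudes >= th), "hilbert", th
    )


def select_peaks(
    candidates: PeakSet, signal: EnhancedSignal, spec: ThresholdSpec
) -> PeakSet:
    """Dispatch to the selection scheme named by ``spec.method``."""
    if spec.method == "fixed":
        return select_fixed(candidates, spec)
    if spec.method == "adaptive":
        return select_adaptive(candidates, spec)
    return select_hilbert(candidates, signal, spec)
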