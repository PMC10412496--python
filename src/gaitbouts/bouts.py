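"""Grouping of selected gait-event peaks into walking bouts.

Consecutive events whose spacing stays below an adaptive duration
threshold TH_d belong to the same bout. TH_d starts at a fixed
initialisation gap (5 s for a single sensor, 3.5 s for the merged
bilateral step train) and, once a bout holds two or more events, adapts
to the walker's cadence: offset + mean(intra-bout event spacing), capped
at the initialisation gap. The offset is 3 s for stride events (single
sensor) and 1.5 s for step events (two sensors). The initialisation value
accommodates very slow gait (cadence ~40 steps/min, stride duration ~3 s).

Bouts that are too short to be true locomotion are discarded: fewer than
5 steps in the dual-sensor configuration, fewer than 3 same-foot strides
in the single-sensor configuration (the smallest count implying at least
five steps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImuRecording, ValidationError, WalkingBout
from .enhancement import EnhancementParams, enhance
from .peaks import PeakSet, ThresholdSpec, detect_candidate_peaks, select_peaks

__all__ = [
    "GroupingParams",
    "group_events",
    "merge_bilateral",
    "filter_true_locomotion",
    "detect_walking_bouts",
]


@dataclass(frozen=True)
class GroupingParams:
    """Adaptive-duration grouping parameters.

    Use :meth:`single_imu` / :meth:`dual_imu` for the published defaults.
    ``gap_cap`` bounds TH_d from above (the hard maximum inter-peak
    duration); ``min_events`` is the smallest retained bout size.
    """

    config: str = "single_imu"
    init_gap: float = 5.0
    update_offset: float = 3.0
    gap_cap: float = 5.0
    min_events: int = 3

    def __post_init__(self) -> None:
        if self.config not in ("single_imu", "dual_imu"):
            raise ValidationError(f"unknown config {self.config!r}")
        if self.init_gap <= 0:
            raise ValidationError("init_gap must be positive")
        if self.update_offset < 0:
            raise ValidationError("update_offset must be non-negative")
        if self.min_events < 1:
            raise ValidationError("min_events must be >= 1")

    @classmethod
    def single_imu(cls, **overrides) -> "GroupingParams":
        """Stride-event grouping: 5 s init/cap, TH_d = 3 + mean stride duration."""
        kw = dict(config="single_imu", init_gap=5.0, update_offset=3.0,
                  gap_cap=5.0, min_events=3)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def dual_imu(cls, **overrides) -> "GroupingParams":
        """Step-event grouping: 3.5 s init/cap, TH_d = 1.5 + mean step duration."""
        kw = dict(config="dual_imu", init_gap=3.5, update_offset=1.5,
                  gap_cap=3.5, min_events=5)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def for_config(cls, config: str, **overrides) -> "GroupingParams":
        return cls.single_imu(**overrides) if config == "single_imu" else cls.dual_imu(**overrides)


def group_events(
    peak_times: np.ndarray, params: GroupingParams, signal_source: str = "gyro"
) -> list[WalkingBout]:
    """Left-to-right scan grouping event times into (unfiltered) bouts.

    The current bout's TH_d is ``init_gap`` while the bout holds a single
    event; from two events on it is
    min(update_offset + mean(intra-bout spacings), gap_cap), recomputed
    after every accepted event. A gap <= TH_d extends the bout; a larger
    gap closes it and starts a new one. Bout start/end are the first/last
    member event times.
    """
    times = np.asarray(peak_times, dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValidationError("peak times must be sorted and strictly increasing")
    bouts: list[WalkingBout] = []
    if times.size == 0:
        return bouts

    def close(members: list[float]) -> None:
        ev = np.asarray(members)
        bouts.append(
            WalkingBout(
                start=ev[0], end=ev[-1], events=ev,
                config=params.config, signal_source=signal_source,
            )
        )

    current = [times[0]]
    th_d = params.init_gap
    for t in times[1:]:
        gap = t - current[-1]
        if gap <= th_d:
            current.append(t)
            mean_dur = (current[-1] - current[0]) / (len(current) - 1)
            th_d = min(params.update_offset + mean_dur, params.gap_cap)
        else:
            close(current)
            current = [t]
            th_d = params.init_gap
    close(current)
    return bouts


def merge_bilateral(left: PeakSet, right: PeakSet) -> np.ndarray:
    """Sorted union of left and right peak times (step-event train).

    Exact ties keep the left event first; the count is always
    ``len(left) + len(right)``.
    """
    order = np.argsort(
        np.concatenate([left.times, right.times]), kind="stable"
    )
    return np.concatenate([left.times, right.times])[order]


def filter_true_locomotion(
    bouts: list[WalkingBout], params: GroupingParams
) -> list[WalkingBout]:
    """Discard bouts with fewer than ``params.min_events`` events."""
    return [b for b in bouts if b.n_events >= params.min_events]


def detect_walking_bouts(
    recordings: ImuRecording | tuple[ImuRecording, ImuRecording],
    spec: ThresholdSpec | None = None,
    eparams: EnhancementParams | None = None,
    gparams: GroupingParams | None = None,
    source: str = "gyro",
) -> list[WalkingBout]:
    """Full pipeline: enhance, select peaks, group, retain true locomotion.

    Pass one recording for the single-sensor configuration or a
    synchronized (left, right) pair for the dual-sensor configuration.
    In the dual case peak selection runs per foot (so thresholds adapt to
    asymmetric gait) before the step trains are merged.
    """
    spec = spec or ThresholdSpec()
    eparams = eparams or EnhancementParams()

    if isinstance(recordings, ImuRecording):
        gparams = gparams or GroupingParams.single_imu()
        sig = enhance(recordings, source, eparams)
        selected = select_peaks(detect_candidate_peaks(sig), sig, spec)
        event_times = selected.times
    else:
        left, right = recordings
        if abs(left.t[0] - right.t[0]) > 1.0 / min(left.fs, right.fs):
            raise ValidationError(
                "dual-sensor recordings are not synchronized "
                "(start-time mismatch exceeds one sample)"
            )
        gparams = gparams or GroupingParams.dual_imu()
        per_foot = []
        for rec in (left, right):
            sig = enhance(rec, source, eparams)
            per_foot.append(select_peaks(detect_candidate_peaks(sig), sig, spec))
        event_times = merge_bilateral(per_foot[0], per_foot[1])

    grouped = group_events(event_times, gparams, signal_source=source)
    return filter_true_locomotion(grouped, gparams)
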