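"""Core domain types shared across the walking-bout detection pipeline.

All times are seconds (float); angular velocity is deg/s and acceleration
is g by contract — units are never auto-detected because the fixed
amplitude thresholds (100 deg/s, 0.5 g) are unit-bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "ImuRecording",
    "LabelVector",
    "WalkingBout",
]


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


@dataclass(frozen=True)
class ImuRecording:
    """Raw multi-axis samples from one foot-worn inertial sensor.

    Parameters
    ----------
    side : {"left", "right", "unspecified"}
        Which foot the sensor is mounted on.
    fs : float
        Sampling rate in Hz; must be consistent with the median sample
        spacing of ``t`` within 1%.
    t : ndarray, shape (n,)
        Strictly increasing sample times in seconds.
    gyro : ndarray, shape (n, 3), optional
        Angular velocity (roll, pitch, yaw) in deg/s.
    acc : ndarray, shape (n, 3), optional
        Acceleration in g.
    """

    side: str
    fs: float
    t: np.ndarray
    gyro: np.ndarray | None = None
    acc: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "unspecified"):
            raise ValidationError(f"unknown side {self.side!r}")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if t.ndim != 1 or t.size == 0:
            raise ValidationError("time vector must be 1-D and non-empty")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("sample times must be strictly increasing")
        if self.gyro is None and self.acc is None:
            raise ValidationError("at least one of gyro/acc must be present")
        for name in ("gyro", "acc"):
            ch = getattr(self, name)
            if ch is None:
                continue
            ch = np.asarray(ch, dtype=float)
            object.__setattr__(self, name, ch)
            if ch.shape != (t.size, 3):
                raise ValidationError(
                    f"{name} must have shape ({t.size}, 3), got {ch.shape}"
                )
        if t.size > 1:
            median_dt = float(np.median(np.diff(t)))
            if abs(1.0 / median_dt - self.fs) > 0.01 * self.fs:
                raise ValidationError(
                    f"fs={self.fs} Hz inconsistent with median sample spacing "
                    f"{median_dt:.6g} s"
                )

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.n_samples / self.fs

    def channel(self, source: str) -> np.ndarray:
        """Return the (n, 3) array for ``source`` in {"gyro", "acc"}."""
        if source not in ("gyro", "acc"):
            raise ValidationError(f"unknown source {source!r}")
        ch = getattr(self, source)
        if ch is None:
            raise ValidationError(f"recording has no {source} channel")
        return ch


@dataclass(frozen=True)
class LabelVector:
    """Per-sample binary locomotion labels (0 = no locomotion, 1 = locomotion)."""

    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError("label rate must be positive")
        v = np.asarray(self.values)
        if v.ndim != 1 or v.size == 0:
            raise ValidationError("label vector must be 1-D and non-empty")
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("labels must be binary (0/1)")
        object.__setattr__(self, "values", v.astype(np.int8))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclass(frozen=True)
class WalkingBout:
    """A contiguous locomotion period delimited by detected gait events.

    ``events`` are stride-event times (single-sensor configuration) or
    merged bilateral step-event times (dual-sensor configuration), on the
    analysis clock.
    """

    start: float
    end: float
    events: np.ndarray = field(default_factory=lambda: np.empty(0))
    config: str = "single_imu"
    signal_source: str = "gyro"

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float)
        object.__setattr__(self, "events", ev)
        if self.config not in ("single_imu", "dual_imu"):
            raise ValidationError(f"unknown config {self.config!r}")
        if self.signal_source not in ("gyro", "acc"):
            raise ValidationError(f"unknown source {self.signal_source!r}")
        if self.end < self.start:
            raise ValidationError("bout end precedes start")
        if ev.size:
            if not np.all(np.diff(ev) >= 0):
                raise ValidationError("bout events must be ordered")
            if ev[0] < self.start - 1e-9 or ev[-1] > self.end + 1e-9:
                raise ValidationError("bout events fall outside [start, end]")

    @property
    def n_events(self) -> int:
        return self.events.size

    @property
    def duration(self) -> float:
        return self.end - self.start
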