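"""Validation of detected walking bouts against reference labels.

Bouts are rasterised to per-sample binary labels (half-open [start, end)
intervals on the analysis clock, 40 Hz by default), compared elementwise
with a reference label vector, and summarised by the standard confusion
rates:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / total     precision   = TP / (TP + FP)

A ratio with zero denominator is reported as NaN, never as 0. The
percentile sweep re-runs the detector over a grid of percentile values
(default 1-50%) for the adaptive or hilbert method and returns the
resulting ROC curve (sensitivity vs 1 - specificity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bouts import GroupingParams, detect_walking_bouts
from .core import ImuRecording, LabelVector, ValidationError, WalkingBout
from .enhancement import EnhancementParams
from .peaks import ThresholdSpec

__all__ = [
    "ConfusionMetrics",
    "RocCurve",
    "default_percentile_grid",
    "bouts_to_labels",
    "labels_to_intervals",
    "majority_per_second",
    "confusion_metrics",
    "roc_sweep",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sample counts and the four derived rates of a binary comparison."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.total)

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC points of the percentile sweep for one method/configuration."""

    percentiles: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    method: str
    config: str

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        t = np.asarray(self.tpr, dtype=float)
        f = np.asarray(self.fpr, dtype=float)
        for name, arr in (("percentiles", p), ("tpr", t), ("fpr", f)):
            object.__setattr__(self, name, arr)
        if not (p.size == t.size == f.size):
            raise ValidationError("ROC arrays must share a length")
        finite_t, finite_f = t[np.isfinite(t)], f[np.isfinite(f)]
        if ((finite_t < 0) | (finite_t > 1)).any() or (
            (finite_f < 0) | (finite_f > 1)
        ).any():
            raise ValidationError("ROC points must lie in the unit square")


def default_percentile_grid() -> np.ndarray:
    """The published sweep: 1% plus the multiples of 2.5% up to 50%."""
    return np.concatenate(([1.0], np.arange(2.5, 50.0 + 1e-9, 2.5)))


def bouts_to_labels(
    bouts: list[WalkingBout], duration: float, fs: float = 40.0
) -> LabelVector:
    """Rasterise bouts to a binary vector of round(duration * fs) samples.

    Sample k (time k/fs) is labelled 1 iff it falls in some half-open
    [start, end) bout interval; adjacent bouts therefore tile without
    double counting.
    """
    n = int(round(duration * fs))
    if n <= 0:
        raise ValidationError("duration must cover at least one sample")
    values = np.zeros(n, dtype=np.int8)
    for b in bouts:
        if b.start < -1e-9 or b.end > duration + 1e-9:
            raise ValidationError(
                f"bout [{b.start}, {b.end}] outside [0, {duration}]"
            )
        lo = int(np.ceil(b.start * fs - 1e-9))
        hi = int(np.ceil(b.end * fs - 1e-9))  # exclusive: k/fs < end
        values[max(lo, 0) : min(hi, n)] = 1
    return LabelVector(fs=fs, values=values)


def labels_to_intervals(labels: LabelVector) -> list[tuple[float, float]]:
    """Half-open (start, end) intervals of the 1-runs of a label vector."""
    padded = np.concatenate(([0], labels.values, [0]))
    edges = np.flatnonzero(np.diff(padded))
    return [
        (s / labels.fs, e / labels.fs) for s, e in zip(edges[::2], edges[1::2])
    ]


def majority_per_second(labels: LabelVector) -> LabelVector:
    """Optional coarse view: one 0/1 per second by majority vote.

    Provided for evaluations that assign a single label per second rather
    than per sample; ties (exactly half the samples positive) count as 1.
    """
    n_per = int(round(labels.fs))
    n_sec = int(np.ceil(len(labels) / n_per))
    padded = np.zeros(n_sec * n_per, dtype=float)
    padded[: len(labels)] = labels.values
    votes = padded.reshape(n_sec, n_per).mean(axis=1)
    return LabelVector(fs=1.0, values=(votes >= 0.5).astype(np.int8))


def confusion_metrics(pred: LabelVector, ref: LabelVector) -> ConfusionMetrics:
    """Elementwise confusion counts of prediction vs reference labels."""
    if len(pred) != len(ref):
        raise ValidationError(
            f"label length mismatch: pred {len(pred)} vs ref {len(ref)}"
        )
    if abs(pred.fs - ref.fs) > 1e-9:
        raise ValidationError("label rates differ")
    p, r = pred.values.astype(bool), ref.values.astype(bool)
    return ConfusionMetrics(
        tp=int(np.sum(p & r)),
        tn=int(np.sum(~p & ~r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
    )


def roc_sweep(
    recordings: ImuRecording | tuple[ImuRecording, ImuRecording],
    reference: LabelVector,
    method: str = "adaptive",
    grid: np.ndarray | None = None,
    spec: ThresholdSpec | None = None,
    eparams: EnhancementParams | None = None,
    gparams: GroupingParams | None = None,
    source: str = "gyro",
) -> RocCurve:
    """Detector performance across the percentile grid.

    Runs the full detection pipeline once per percentile value and
    compares the rasterised prediction with ``reference`` (whose rate and
    duration define the evaluation raster).
    """
    if method not in ("adaptive", "hilbert"):
        raise ValidationError("roc sweep applies to the adaptive/hilbert methods")
    grid = default_percentile_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValidationError("empty percentile grid")
    if ((grid <= 0) | (grid > 50)).any():
        raise ValidationError("percentile grid must lie in (0, 50]")
    base = spec or ThresholdSpec()
    config = "single_imu" if isinstance(recordings, ImuRecording) else "dual_imu"
    duration = reference.duration
    tpr, fpr = [], []
    for p in grid:
        sp = ThresholdSpec(
            method=method,
            fixed_gyro=base.fixed_gyro,
            fixed_acc=base.fixed_acc,
            percentile=float(p),
            hilbert_preselect_min_dur=base.hilbert_preselect_min_dur,
            hilbert_gap_merge=base.hilbert_gap_merge,
        )
        bouts = detect_walking_bouts(recordings, sp, eparams, gparams, source)
        pred = bouts_to_labels(bouts, duration, reference.fs)
        m = confusion_metrics(pred, reference)
        tpr.append(m.sensitivity)
        fpr.append(1.0 - m.specificity)
    return RocCurve(
        percentiles=grid, tpr=np.asarray(tpr), fpr=np.asarray(fpr),
        method=method, config=config,
    )
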