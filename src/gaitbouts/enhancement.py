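"""Stride-peak enhancement of foot-worn IMU signals.

The chain turns a raw 3-axis gyroscope (or accelerometer) recording into a
smooth, orientation-invariant scalar series whose local maxima mark
mid-swing (gyroscope) or heel-strike (accelerometer) events:

1. Euclidean norm of the 3-axis signal (orientation-invariant, so no
   sensor-to-segment calibration is needed).
2. Downsampling to the 40 Hz analysis rate (anti-aliased polyphase).
3. Linear detrend followed by zero-phase FIR low-pass filtering
   (windowed-sinc, 120 coefficients, cutoff ~3.2 Hz, applied forward and
   backward so peaks are not displaced).
4. Single-scale continuous wavelet transform with a second-derivative-of-
   Gaussian (gaus2) kernel at scale 15, acting as combined smoothing and
   differentiation tuned to stride periodicity (~0.8 Hz pseudo-frequency
   at 40 Hz).
5. A light linear Savitzky-Golay smoothing pass.

The result is the enhanced norm on which amplitude thresholding selects
stride/step-related peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .core import ImuRecording, ValidationError

__all__ = [
    "EnhancementParams",
    "EnhancedSignal",
    "compute_norm",
    "resample_to_analysis_rate",
    "zero_phase_lowpass",
    "cwt_enhance",
    "savgol_smooth",
    "enhance",
]

# pywt's gaus2 kernel is -(d^2/dx^2)Gaussian up to normalisation, so the
# single-scale coefficient of a positive bump is already a positive central
# maximum; no sign flip is needed. Kept explicit so the orientation of the
# output (positive mid-swing peaks) is pinned down in one place.
_CWT_SIGN = 1.0


@dataclass(frozen=True)
class EnhancementParams:
    """Parameters of the peak-enhancement chain.

    Defaults are the published operating point: 40 Hz analysis rate,
    120-coefficient FIR low-pass at ~3.2 Hz, gaus2 wavelet scale 15,
    and an 11-sample linear Savitzky-Golay smoother.
    """

    analysis_fs: float = 40.0
    fir_order: int = 120
    fir_cutoff: float = 3.2
    cwt_scale: float = 15.0
    savgol_window: int = 11
    savgol_order: int = 1

    def __post_init__(self) -> None:
        if self.analysis_fs <= 2.0 * self.fir_cutoff:
            raise ValidationError("analysis_fs must exceed twice the FIR cutoff")
        if self.savgol_window % 2 == 0 or self.savgol_window < self.savgol_order + 1:
            raise ValidationError("savgol_window must be odd and > savgol_order")
        if self.cwt_scale <= 0:
            raise ValidationError("cwt_scale must be positive")
        if self.fir_order < 2:
            raise ValidationError("fir_order must be >= 2")

    def scale_at(self, analysis_fs: float) -> float:
        """Wavelet scale rescaled if a non-default analysis rate is used.

        The default scale (15) is defined at 40 Hz; rescaling keeps the
        enhanced band aligned with stride frequency.
        """
        return self.cwt_scale * analysis_fs / 40.0


@dataclass(frozen=True)
class EnhancedSignal:
    """The enhanced norm at the analysis rate.

    ``values`` carry the units of the source channel (deg/s for gyro,
    g for acc). ``intermediates`` optionally retains the raw norm and the
    low-pass-filtered norm for diagnostics.
    """

    fs: float
    values: np.ndarray
    source: str
    intermediates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.source not in ("gyro", "acc"):
            raise ValidationError(f"unknown source {self.source!r}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("enhanced signal contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


def compute_norm(samples: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of per-sample 3-vectors.

    For the gyroscope this is sqrt(w_roll^2 + w_pitch^2 + w_yaw^2) — the
    orientation-invariant scalar the whole pipeline operates on.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValidationError("empty input")
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) samples, got {samples.shape}")
    return np.linalg.norm(samples, axis=1)


def resample_to_analysis_rate(
    series: np.ndarray, raw_fs: float, analysis_fs: float
) -> np.ndarray:
    """Anti-alias-filtered downsampling from ``raw_fs`` to ``analysis_fs``.

    Upsampling is refused: the analysis rate is meant to reduce long-term
    monitoring data, not to interpolate it.
    """
    series = np.asarray(series, dtype=float)
    if raw_fs < analysis_fs:
        raise ValidationError("raw_fs must be >= analysis_fs (no upsampling)")
    if raw_fs == analysis_fs:
        return series.copy()
    ratio = Fraction(analysis_fs).limit_denominator(10_000) / Fraction(
        raw_fs
    ).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    # explicit Kaiser-windowed anti-alias filter, normalised to unit DC
    # gain so constants survive exactly; padtype="line" tames the edges
    max_rate = max(up, down)
    taps = sps.firwin(2 * 10 * max_rate + 1, 1.0 / max_rate, window=("kaiser", 5.0))
    taps /= taps.sum()
    # resampling around the mean lets the DC component through exactly
    # (the polyphase branches of the anti-alias filter are not perfectly
    # DC-balanced), so a constant input maps to the same constant
    mean = float(series.mean())
    return (
        sps.resample_poly(series - mean, up, down, window=taps, padtype="line")
        + mean
    )


def zero_phase_lowpass(series: np.ndarray, params: EnhancementParams) -> np.ndarray:
    """Linear detrend + forward-backward FIR low-pass (zero phase).

    The FIR filter is a Hamming-windowed sinc of ``fir_order`` coefficients
    with cutoff ``fir_cutoff`` at the analysis rate. Applying it in both
    directions cancels the group delay, so symmetric peaks stay put.
    """
    series = np.asarray(series, dtype=float)
    if series.size <= 3 * params.fir_order:
        raise ValidationError(
            f"series too short for zero-phase filtering "
            f"(need > {3 * params.fir_order} samples, got {series.size})"
        )
    detrended = sps.detrend(series, type="linear")
    taps = sps.firwin(params.fir_order, params.fir_cutoff, fs=params.analysis_fs)
    return sps.filtfilt(taps, [1.0], detrended)


def _gaus2_cwt(series: np.ndarray, scale: float) -> np.ndarray:
    pad = int(np.ceil(5 * scale)) + 1
    padded = np.pad(series, pad, mode="symmetric")
    coeffs, _ = pywt.cwt(padded, [scale], "gaus2")
    return _CWT_SIGN * coeffs[0, pad : pad + series.size]


def cwt_enhance(series: np.ndarray, params: EnhancementParams) -> np.ndarray:
    """Single-scale gaus2 continuous wavelet transform.

    Convolution with the second-derivative-of-Gaussian kernel dilated to
    ``cwt_scale`` analysis-rate samples, oriented so a positive bump in the
    input yields a positive local maximum at the bump centre. Symmetric
    reflection padding keeps the output the same length as the input and
    avoids spurious boundary peaks.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValidationError("empty input")
    return _gaus2_cwt(series, params.scale_at(params.analysis_fs))


def savgol_smooth(series: np.ndarray, params: EnhancementParams) -> np.ndarray:
    """Light Savitzky-Golay smoothing (default: linear fit, 11 samples)."""
    series = np.asarray(series, dtype=float)
    if series.size < params.savgol_window:
        raise ValidationError("series shorter than the Savitzky-Golay window")
    return sps.savgol_filter(
        series, params.savgol_window, params.savgol_order, mode="interp"
    )


def enhance(
    recording: ImuRecording,
    source: str = "gyro",
    params: EnhancementParams | None = None,
    keep_intermediates: bool = False,
) -> EnhancedSignal:
    """Run the full enhancement chain on one recording channel.

    norm -> downsample to analysis rate -> detrend + zero-phase low-pass
    -> gaus2 CWT -> Savitzky-Golay. Returns the enhanced norm at
    ``params.analysis_fs``.
    """
    params = params or EnhancementParams()
    raw_norm = compute_norm(recording.channel(source))
    norm_ds = resample_to_analysis_rate(raw_norm, recording.fs, params.analysis_fs)
    lpf = zero_phase_lowpass(norm_ds, params)
    cwt = cwt_enhance(lpf, params)
    smooth = savgol_smooth(cwt, params)
    intermediates = {}
    if keep_intermediates:
        intermediates = {"norm": norm_ds, "norm_lpf": lpf, "norm_lpf_cwt": cwt}
    return EnhancedSignal(
        fs=params.analysis_fs,
        values=smooth,
        source=source,
        intermediates=intermediates,
    )
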