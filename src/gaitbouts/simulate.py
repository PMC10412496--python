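"""Synthetic foot-worn IMU gait signals with ground-truth labels.

The generator emulates the signal features the detector relies on, not a
full biomechanical model: within each walking bout every stride
contributes a dominant smooth mid-swing angular-velocity bump on the
(pre-rotation) pitch axis, flanked by smaller heel-strike/toe-off ripples
on the other axes; rest periods carry white sensor noise; optional
movement artifacts are isolated 0.5-2 s oscillatory shakes outside the
bouts whose amplitudes straddle the 100 deg/s fixed threshold. The
acceleration channels carry the gravity projection, heel-strike impact
transients and noise. A random fixed mounting rotation is always applied
to the 3-axis data, so every downstream test exercises the
orientation-invariance of the norm-based pipeline.

Bilateral mode returns a synchronized left/right pair with left strides
offset by half a stride and scaled by an asymmetry ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImuRecording, LabelVector, ValidationError

__all__ = ["SimConfig", "SimBout", "GroundTruth", "simulate_recording",
           "make_toy_fixture", "TOY_FIXTURES"]

_MIN_REST = 8.0  # s between bouts; exceeds the 5 s grouping cap


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for the gait-signal generator.

    Defaults describe unimpaired free walking: stride duration 0.9-1.4 s
    (cadence ~86-133 steps/min), mid-swing peak amplitude 250-500 deg/s,
    rest-noise standard deviation 5 deg/s, and two movement artifacts per
    minute with raw amplitudes 80-250 deg/s.
    """

    seed: int = 0
    duration: float = 120.0
    fs: float = 100.0
    n_bouts: int = 3
    stride_duration_range: tuple[float, float] = (0.9, 1.4)
    midswing_amp_range: tuple[float, float] = (250.0, 500.0)
    rest_noise_std: float = 5.0
    artifact_rate: float = 2.0
    artifact_amp_range: tuple[float, float] = (80.0, 250.0)
    bilateral: bool = False
    asymmetry_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("stride_duration_range", "midswing_amp_range",
                     "artifact_amp_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be ordered and positive")
        if self.fs < 40:
            raise ValidationError("fs must be >= 40 Hz")
        if self.n_bouts < 0 or self.duration <= 0:
            raise ValidationError("invalid duration/n_bouts")
        if self.asymmetry_ratio <= 0:
            raise ValidationError("asymmetry_ratio must be positive")

    @property
    def min_bout_duration(self) -> float:
        """Room for at least five strides of the slowest configured gait."""
        return 5.0 * self.stride_duration_range[1] + 1.0


@dataclass(frozen=True)
class SimBout:
    """One ground-truth walking bout with its per-foot stride times."""

    start: float
    end: float
    stride_times_left: np.ndarray
    stride_times_right: np.ndarray

    @property
    def all_strides(self) -> np.ndarray:
        return np.sort(
            np.concatenate([self.stride_times_left, self.stride_times_right])
        )


@dataclass(frozen=True)
class GroundTruth:
    """Reference labels and bout structure of a simulated recording."""

    labels: LabelVector
    bouts: list[SimBout] = field(default_factory=list)

    def label_vector(self, fs: float) -> LabelVector:
        """Rasterise the bout intervals at an arbitrary rate (half-open)."""
        n = int(round(self.labels.duration * fs))
        values = np.zeros(n, dtype=np.int8)
        for b in self.bouts:
            lo = int(np.ceil(b.start * fs - 1e-9))
            hi = int(np.ceil(b.end * fs - 1e-9))
            values[max(lo, 0) : min(hi, n)] = 1
        return LabelVector(fs=fs, values=values)

    @property
    def n_strides(self) -> int:
        return sum(b.all_strides.size for b in self.bouts)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (normalised 4-normal quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _layout_bouts(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place n_bouts segments separated by rests of at least _MIN_REST s."""
    if cfg.n_bouts == 0:
        return []
    avail = cfg.duration - (cfg.n_bouts + 1) * _MIN_REST
    min_bout = cfg.min_bout_duration
    if avail < cfg.n_bouts * min_bout:
        raise ValidationError(
            f"duration {cfg.duration} s cannot fit {cfg.n_bouts} bouts of "
            f">= {min_bout:.1f} s plus rests"
        )
    extra_total = 0.75 * (avail - cfg.n_bouts * min_bout)
    w = rng.uniform(0.5, 1.5, cfg.n_bouts)
    durs = min_bout + extra_total * w / w.sum()
    slack = cfg.duration - durs.sum() - (cfg.n_bouts + 1) * _MIN_REST
    g = rng.uniform(0.5, 1.5, cfg.n_bouts + 1)
    rests = _MIN_REST + slack * g / g.sum()
    segments, t = [], 0.0
    for i in range(cfg.n_bouts):
        t += rests[i]
        segments.append((t, t + durs[i]))
        t += durs[i]
    return segments


def _stride_train(
    seg: tuple[float, float], sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Mid-swing instants filling a bout segment at stride duration sd."""
    t0, t1 = seg
    times = [t0 + 0.5 * sd]
    while True:
        nxt = times[-1] + sd * (1.0 + rng.uniform(-0.05, 0.05))
        if nxt > t1 - 0.5 * sd:
            break
        times.append(nxt)
    return np.asarray(times)


def _add_bump(y: np.ndarray, t: np.ndarray, tc: float, amp: float, sigma: float) -> None:
    lo = np.searchsorted(t, tc - 5 * sigma)
    hi = np.searchsorted(t, tc + 5 * sigma)
    y[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - tc) / sigma) ** 2)


def _foot_signal(
    cfg: SimConfig,
    t: np.ndarray,
    bouts: list[SimBout],
    foot: str,
    amp_scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-rotation (n, 3) gyro [deg/s] and acc [g] series for one foot."""
    n = t.size
    gyro = np.zeros((n, 3))
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0  # gravity along the pre-rotation vertical
    for b in bouts:
        strides = b.stride_times_left if foot == "left" else b.stride_times_right
        if strides.size < 2:
            continue
        sd = float(np.median(np.diff(strides)))
        sigma = 0.12 * sd
        for tc in strides:
            amp = amp_scale * rng.uniform(*cfg.midswing_amp_range)
            _add_bump(gyro[:, 1], t, tc, amp, sigma)  # mid-swing, pitch axis
            _add_bump(gyro[:, 0], t, tc + 0.45 * sd, 0.25 * amp, 0.6 * sigma)
            _add_bump(gyro[:, 2], t, tc - 0.40 * sd, 0.20 * amp, 0.6 * sigma)
            # heel-strike impact shortly after mid-swing
            _add_bump(acc[:, 2], t, tc + 0.45 * sd, rng.uniform(0.9, 1.8), 0.06)
            _add_bump(acc[:, 0], t, tc + 0.45 * sd, rng.uniform(0.2, 0.5), 0.06)
    gyro += rng.normal(0.0, cfg.rest_noise_std, size=gyro.shape)
    acc += rng.normal(0.0, 0.02, size=acc.shape)
    return gyro, acc


def _add_artifacts(
    cfg: SimConfig,
    t: np.ndarray,
    gyro: np.ndarray,
    bouts: list[SimBout],
    rng: np.random.Generator,
) -> None:
    """Isolated oscillatory shakes in the rest periods."""
    n_art = rng.poisson(cfg.artifact_rate * cfg.duration / 60.0)
    margin = 2.5
    forbidden = [(b.start - margin, b.end + margin) for b in bouts]
    for _ in range(n_art):
        dur = rng.uniform(0.5, 2.0)
        for _try in range(50):
            c = rng.uniform(1.0 + dur, cfg.duration - 1.0 - dur)
            if all(not (lo < c + dur / 2 and c - dur / 2 < hi) for lo, hi in forbidden):
                break
        else:
            continue
        amp = rng.uniform(*cfg.artifact_amp_range)
        freq = rng.uniform(0.8, 3.0)
        axis = rng.integers(0, 3)
        lo = np.searchsorted(t, c - dur / 2)
        hi = np.searchsorted(t, c + dur / 2)
        tt = t[lo:hi] - (c - dur / 2)
        gyro[lo:hi, axis] += (
            amp * np.sin(2 * np.pi * freq * tt) * np.hanning(tt.size)
        )


def simulate_recording(
    config: SimConfig,
) -> tuple[ImuRecording | tuple[ImuRecording, ImuRecording], GroundTruth]:
    """Generate one recording (or a bilateral pair) plus its ground truth.

    Deterministic given ``config.seed``. Ground-truth bout intervals span
    half a stride before the first mid-swing to half a stride after the
    last one (the locomotion period, not just the detected event span).
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(int(round(config.duration * config.fs))) / config.fs
    segments = _layout_bouts(config, rng)

    sim_bouts: list[SimBout] = []
    for seg in segments:
        sd = rng.uniform(*config.stride_duration_range)
        right = _stride_train(seg, sd, rng)
        left = right + 0.5 * sd if config.bilateral else np.empty(0)
        left = left[left <= t[-1]]
        strides = np.sort(np.concatenate([left, right]))
        sim_bouts.append(
            SimBout(
                start=float(strides[0] - 0.5 * sd),
                end=float(strides[-1] + 0.5 * sd),
                stride_times_left=left,
                stride_times_right=right,
            )
        )

    def build(foot: str, amp_scale: float, side: str) -> ImuRecording:
        gyro, acc = _foot_signal(config, t, sim_bouts, foot, amp_scale, rng)
        _add_artifacts(config, t, gyro, sim_bouts, rng)
        rot = _random_rotation(rng)
        return ImuRecording(
            side=side, fs=config.fs, t=t, gyro=gyro @ rot.T, acc=acc @ rot.T
        )

    values = np.zeros(t.size, dtype=np.int8)
    for b in sim_bouts:
        lo = int(np.ceil(b.start * config.fs - 1e-9))
        hi = int(np.ceil(b.end * config.fs - 1e-9))
        values[max(lo, 0) : min(hi, t.size)] = 1
    truth = GroundTruth(labels=LabelVector(config.fs, values), bouts=sim_bouts)

    if config.bilateral:
        right_rec = build("right", 1.0, "right")
        left_rec = build("left", config.asymmetry_ratio, "left")
        return (left_rec, right_rec), truth
    return build("right", 1.0, "unspecified"), truth


TOY_FIXTURES = {
    "clean_walk": SimConfig(seed=11, duration=26.0, n_bouts=1, artifact_rate=0.0),
    "slow_walk": SimConfig(
        seed=12, duration=60.0, n_bouts=1, artifact_rate=0.0,
        stride_duration_range=(2.5, 3.0), midswing_amp_range=(150.0, 250.0),
    ),
    "artifact_storm": SimConfig(
        seed=13, duration=60.0, n_bouts=1, artifact_rate=20.0,
        artifact_amp_range=(120.0, 300.0),
    ),
    "asymmetric_dual": SimConfig(
        seed=14, duration=50.0, n_bouts=1, bilateral=True,
        asymmetry_ratio=0.7, artifact_rate=0.0,
    ),
    "rest_only": SimConfig(seed=15, duration=45.0, n_bouts=0, artifact_rate=0.0),
}


def make_toy_fixture(name: str):
    """Small (<= 60 s) named scenarios with documented detector behavior.

    ``rest_only`` yields no bouts under any method; ``clean_walk`` is one
    unimpaired bout; ``slow_walk`` stresses the 5 s inter-stride cap;
    ``artifact_storm`` separates the fixed and adaptive methods;
    ``asymmetric_dual`` is a bilateral pair with a weaker left side.
    """
    if name not in TOY_FIXTURES:
        raise ValidationError(
            f"unknown fixture {name!r}; choose from {sorted(TOY_FIXTURES)}"
        )
    return simulate_recording(TOY_FIXTURES[name])
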