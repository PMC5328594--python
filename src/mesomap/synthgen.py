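"""Ground-truth synthetic sessions for spike-triggered mapping.

The generator emulates the statistical structure the mapping assumes: one or
more spatial motifs (sums of 2-D Gaussian blobs, optionally bilateral)
coupled to Poisson spike trains through a calcium-indicator impulse
response, riding on a positive per-pixel baseline, plus i.i.d. pixel noise,
a shared multiplicative low-frequency artifact that also drives a
reflectance channel (emulating blood-volume common mode), occasional
background motifs not locked to any unit, and a behavior video with planted
quiet/movement epochs.

Model for the green channel::

    F_g(t, x) = F0(x) * (1 + sum_u c_u m_u(x) (k_u * s_u)(t)
                           + sum_b m_b(x) (k_b * o_b)(t)
                           + eps(t, x)) * (1 + a h(t))

and for the reflectance channel ``F_b(t, x) = B0(x) (1 + a h(t) + eps_b)``,
where ``h`` is unit-variance low-pass noise, ``s_u`` are Poisson spike
trains, ``o_b`` Poisson occurrence trains, and ``eps`` is Gaussian pixel
noise. Fixing the seed makes the whole session bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import ImagingStack, SpikeTrain, times_to_frames

__all__ = [
    "MotifSpec",
    "SynthConfig",
    "GroundTruth",
    "gaussian_motif",
    "indicator_kernel",
    "make_stmtd_prototype",
    "poisson_spike_times",
    "generate_session",
    "generate_behavior",
]


@dataclass
class MotifSpec:
    """A spatial activation pattern and its per-event temporal kernel.

    ``spatial_map`` holds H x W weights (peak normalised to 1 by the blob
    helpers); ``temporal_kernel`` is a finite impulse response in ΔF/F0
    fraction per event, sampled at the session frame rate, starting at the
    event frame.
    """

    spatial_map: np.ndarray
    temporal_kernel: np.ndarray
    label: str = "motif"

    def __post_init__(self) -> None:
        self.spatial_map = np.asarray(self.spatial_map, dtype=np.float64)
        self.temporal_kernel = np.asarray(self.temporal_kernel, dtype=np.float64)
        if not np.all(np.isfinite(self.spatial_map)):
            raise ValueError("spatial_map must be finite")


@dataclass
class UnitSpec:
    motif: MotifSpec
    firing_rate_hz: float = 2.0
    coupling: float = 0.05  # peak ΔF/F0 fraction per spike
    location: str = "cortical"


@dataclass
class BackgroundSpec:
    motif: MotifSpec
    occurrence_rate_hz: float = 0.2
    amplitude: float = 0.04


@dataclass
class SynthConfig:
    """Study conditions for one synthetic session.

    Defaults describe a 64 x 64, 30 Hz, 300 s recording with 1% per-pixel
    frame noise and a 2% hemodynamic common-mode artifact below 0.3 Hz.
    """

    n_frames: int = 9000
    frame_rate_hz: float = 30.0
    height: int = 64
    width: int = 64
    baseline_f0: float | np.ndarray = 1000.0
    units: list[UnitSpec] = field(default_factory=list)
    background_motifs: list[BackgroundSpec] = field(default_factory=list)
    noise_sd: float = 0.01
    hemo_amplitude: float = 0.02
    hemo_lowpass_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(np.asarray(self.baseline_f0) <= 0):
            raise ValueError("baseline_F0 must be positive everywhere")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    unit_motifs: dict[str, np.ndarray]
    unit_kernels: dict[str, np.ndarray]
    unit_couplings: dict[str, float]
    spike_times: dict[str, np.ndarray]
    background_motifs: list[np.ndarray]
    background_times: list[np.ndarray]
    hemo_trace: np.ndarray | None = None
    quiet_intervals: list[tuple[float, float]] = field(default_factory=list)
    movement_intervals: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Building blocks


def gaussian_motif(height: int, width: int, centers: list[tuple[float, float]],
                   sigma_px: float = 6.0, label: str = "motif",
                   kernel: np.ndarray | None = None) -> MotifSpec:
    """Sum of isotropic Gaussian blobs, peak-normalised to 1.

    ``centers`` are (row, col) pairs; pass two mirrored centers for a
    bilateral motif.
    """
    rr, cc = np.mgrid[0:height, 0:width]
    m = np.zeros((height, width))
    for r0, c0 in centers:
        m += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2))
    m /= m.max()
    if kernel is None:
        kernel = indicator_kernel(30.0)
    return MotifSpec(spatial_map=m, temporal_kernel=kernel, label=label)


def indicator_kernel(frame_rate_hz: float, rise_tau_s: float = 0.08,
                     decay_tau_s: float = 0.4, duration_s: float = 3.0) -> np.ndarray:
    """Difference-of-exponentials calcium impulse response, peak 1.

    Rise 80 ms / decay 400 ms by default, which places the kernel peak in
    the 100–200 ms range typical of fast genetically encoded indicators.
    """
    t = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: decay tau must exceed rise tau")
    return k / peak


def make_stmtd_prototype(pattern: int, frame_rate_hz: float,
                         window_s: tuple[float, float] = (-3.0, 3.0)) -> np.ndarray:
    """Closed-form prototype of one of the three event-triggered temporal
    dynamics classes, over −3…+3 s.

    pattern 1, spike-triggered excitation: zero before the event, a positive
    transient peaking ~0.15 s after it, decaying back to zero.
    pattern 2, spike-triggered inhibition: zero before the event, then a
    slow negative deflection lasting up to ~3 s.
    pattern 3, inhibition-triggered spiking: activity already depressed
    before the event, a brief rebound near the event, then renewed
    depression.

    Returns the kernel sampled on the session frame grid; amplitudes are in
    ΔF/F0 fraction with extremum magnitude 1.
    """
    lo, hi = window_s
    t = np.arange(round(lo * frame_rate_hz), round(hi * frame_rate_hz) + 1) / frame_rate_hz
    if pattern == 1:
        k = np.where(t >= 0, np.exp(-t / 0.5) - np.exp(-t / 0.08), 0.0)
    elif pattern == 2:
        k = np.where(t >= 0, -(np.exp(-t / 1.2) - np.exp(-t / 0.25)), 0.0)
    elif pattern == 3:
        pre = -0.6 * np.exp(-((t + 1.2) ** 2) / (2 * 0.8**2))
        rebound = np.where(t >= 0, np.exp(-t / 0.25) - np.exp(-t / 0.05), 0.0)
        post = np.where(t >= 0.0, -(np.exp(-t / 1.5) - np.exp(-t / 0.35)), 0.0)
        k = pre + 0.8 * rebound + post
    else:
        raise ValueError(f"unknown prototype pattern {pattern!r}; expected 1, 2 or 3")
    return k / np.abs(k).max()


def poisson_spike_times(rate_hz: float, duration_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times on [0, duration)."""
    n = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    # strictly increasing for SpikeTrain: jitter exact ties by one ns
    while np.any(np.diff(times) <= 0):
        dup = np.where(np.diff(times) <= 0)[0] + 1
        times[dup] += 1e-9
        times = np.sort(times)
    return times


def _event_drive(times_s: np.ndarray, kernel: np.ndarray, n_frames: int,
                 frame_rate_hz: float) -> np.ndarray:
    """Convolve a delta train (one per event frame) with a causal kernel."""
    drive = np.zeros(n_frames)
    frames, _ = times_to_frames(times_s, frame_rate_hz, n_frames)
    counts = np.bincount(frames, minlength=n_frames).astype(np.float64)
    full = np.convolve(counts, kernel)[:n_frames]
    drive += full
    return drive


# ---------------------------------------------------------------------------
# Session generation


def generate_session(config: SynthConfig) -> tuple[ImagingStack, ImagingStack, list[SpikeTrain], GroundTruth]:
    """Generate one synthetic session: green fluorescence stack, blue
    reflectance stack, spike trains and the planted ground truth.

    With ``noise_sd = 0`` and ``hemo_amplitude = 0`` the green stack equals
    ``F0 * (1 + sum_u c_u m_u (k_u * s_u))`` exactly; identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    T, H, W = config.n_frames, config.height, config.width
    f0 = np.broadcast_to(np.asarray(config.baseline_f0, dtype=np.float64), (H, W))

    frac = np.zeros((T, H, W), dtype=np.float32)  # ΔF/F0 fraction component
    trains: list[SpikeTrain] = []
    truth = GroundTruth(unit_motifs={}, unit_kernels={}, unit_couplings={},
                        spike_times={}, background_motifs=[], background_times=[])

    for i, unit in enumerate(config.units):
        uid = unit.motif.label if unit.motif.label != "motif" else f"unit{i}"
        times = poisson_spike_times(unit.firing_rate_hz, config.duration_s, rng)
        drive = _event_drive(times, unit.motif.temporal_kernel, T, config.frame_rate_hz)
        frac += (unit.coupling * drive[:, None, None] * unit.motif.spatial_map[None]).astype(np.float32)
        trains.append(SpikeTrain(times_s=times, unit_id=uid, peak_to_peak_uv=80.0,
                                 location=unit.location))
        truth.unit_motifs[uid] = unit.motif.spatial_map.copy()
        truth.unit_kernels[uid] = unit.motif.temporal_kernel.copy()
        truth.unit_couplings[uid] = unit.coupling
        truth.spike_times[uid] = times

    for bg in config.background_motifs:
        times = poisson_spike_times(bg.occurrence_rate_hz, config.duration_s, rng)
        drive = _event_drive(times, bg.motif.temporal_kernel, T, config.frame_rate_hz)
        frac += (bg.amplitude * drive[:, None, None] * bg.motif.spatial_map[None]).astype(np.float32)
        truth.background_motifs.append(bg.motif.spatial_map.copy())
        truth.background_times.append(times)

    if config.noise_sd > 0:
        frac += rng.normal(0.0, config.noise_sd, size=(T, H, W)).astype(np.float32)

    if config.hemo_amplitude > 0:
        h = _lowpass_noise(T, config.frame_rate_hz, config.hemo_lowpass_hz, rng)
    else:
        h = np.zeros(T)
    truth.hemo_trace = h
    hemo = (1.0 + config.hemo_amplitude * h).astype(np.float32)

    green = (f0[None].astype(np.float32) * (1.0 + frac) * hemo[:, None, None])
    b0 = 0.5 * f0
    eps_b = rng.normal(0.0, 0.002, size=(T, H, W)).astype(np.float32)
    blue = b0[None].astype(np.float32) * (1.0 + config.hemo_amplitude * h[:, None, None].astype(np.float32) + eps_b)

    green_stack = ImagingStack(green, config.frame_rate_hz, channel="green_fluorescence")
    blue_stack = ImagingStack(blue, config.frame_rate_hz, channel="blue_reflectance")
    return green_stack, blue_stack, trains, truth


def _lowpass_noise(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed below ``cutoff_hz``."""
    x = rng.normal(size=n)
    if n < 30:
        return x - x.mean()
    sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return (y - y.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# Behavior video


def generate_behavior(n_frames: int, frame_rate_hz: float, height: int = 32,
                      width: int = 32,
                      movement_intervals: list[tuple[float, float]] | None = None,
                      seed: int = 0,
                      texture_amplitude: float = 50.0) -> tuple[ImagingStack, GroundTruth]:
    """Behavior-camera video with planted quiet/movement epochs.

    The video is constant (zero frame-to-frame gradient) inside quiet
    epochs and shows a moving textured patch inside each movement interval.
    Returns the video and a :class:`GroundTruth` whose ``quiet_intervals``
    and ``movement_intervals`` are the planted epochs.
    """
    duration = n_frames / frame_rate_hz
    movement_intervals = list(movement_intervals or [])
    for a, b in movement_intervals:
        if not (0 <= a < b <= duration):
            raise ValueError(f"movement interval ({a}, {b}) outside session [0, {duration:.2f}]")
    rng = np.random.default_rng(seed)
    base = 100.0 + 10.0 * rng.random((height, width))
    video = np.repeat(base[None].astype(np.float32), n_frames, axis=0)
    t = np.arange(n_frames) / frame_rate_hz
    moving = np.zeros(n_frames, dtype=bool)
    for a, b in movement_intervals:
        moving |= (t >= a) & (t < b)
    patch = texture_amplitude * rng.random((height // 2, width // 2)).astype(np.float32)
    for i in np.where(moving)[0]:
        # patch jitters every frame -> nonzero inter-frame gradient
        r = int(rng.integers(0, height // 2))
        c = int(rng.integers(0, width // 2))
        video[i, r:r + height // 2, c:c + width // 2] += patch

    quiet = _complement_intervals(movement_intervals, duration)
    truth = GroundTruth(unit_motifs={}, unit_kernels={}, unit_couplings={},
                        spike_times={}, background_motifs=[], background_times=[],
                        quiet_intervals=quiet, movement_intervals=movement_intervals)
    stack = ImagingStack(video, frame_rate_hz, channel="behavior")
    return stack, truth


def _complement_intervals(intervals: list[tuple[float, float]], duration: float) -> list[tuple[float, float]]:
    out = []
    cursor = 0.0
    for a, b in sorted(intervals):
        if a > cursor:
            out.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < duration:
        out.append((cursor, duration))
    return out
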