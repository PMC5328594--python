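"""ΔF/F0, filtering, global-signal regression, hemodynamic correction,
AR deconvolution and spectral profiling.

ΔF/F0 is carried as a dimensionless fraction throughout; multiply by 100
for the percent values shown in figures. Two baselines are supported: the
event-wise baseline (mean of the −3…0 s window before each trigger) and
the global baseline (mean over the whole recording).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import ImagingStack

logger = logging.getLogger("mesomap")

__all__ = [
    "EventTensor",
    "event_window_frames",
    "dff_event",
    "dff_global",
    "bandpass",
    "regress_global_signal",
    "hemodynamic_correct",
    "deconvolve",
    "estimate_ar_coeffs",
    "roi_power_spectrum",
]


@dataclass
class EventTensor:
    """Per-event ΔF/F0 windows: n_events x T_win x H x W.

    ``window_s`` is (pre, post) relative to the trigger, default (−3, +3);
    ``trigger_frames`` are the source frame indices of the surviving events
    (windows that would cross a recording edge are dropped before
    construction).
    """

    values: np.ndarray
    window_s: tuple[float, float]
    trigger_frames: np.ndarray
    frame_rate_hz: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("EventTensor values must be n_events x T_win x H x W")
        expected = expected_window_length(self.window_s, self.frame_rate_hz)
        if self.values.shape[1] != expected:
            raise ValueError(
                f"T_win {self.values.shape[1]} != round((post-pre)*rate) = {expected}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def window_times(self) -> np.ndarray:
        """Time of each window sample relative to the trigger, seconds."""
        pre, _ = self.window_s
        n = self.values.shape[1]
        offset = int(round(pre * self.frame_rate_hz))
        return (np.arange(n) + offset) / self.frame_rate_hz


def expected_window_length(window_s: tuple[float, float], frame_rate_hz: float) -> int:
    pre, post = window_s
    return int(round((post - pre) * frame_rate_hz))


def event_window_frames(window_s: tuple[float, float], frame_rate_hz: float) -> tuple[int, int]:
    """Frame offsets (pre, post) of the event window; trigger frame is 0."""
    pre, post = window_s
    return int(round(pre * frame_rate_hz)), int(round(post * frame_rate_hz))


def _valid_triggers(trigger_frames: np.ndarray, n_frames: int,
                    pre_f: int, post_f: int) -> tuple[np.ndarray, int]:
    trigger_frames = np.asarray(trigger_frames, dtype=np.int64)
    keep = (trigger_frames + pre_f >= 0) & (trigger_frames + post_f <= n_frames)
    return trigger_frames[keep], int((~keep).sum())


def dff_event(stack: ImagingStack, trigger_frames: np.ndarray,
              window_s: tuple[float, float] = (-3.0, 3.0),
              baseline_s: tuple[float, float] = (-3.0, 0.0)) -> EventTensor:
    """Event-wise ΔF/F0 windows around trigger frames.

    For each event the per-pixel baseline F0 is the mean of the frames in
    ``baseline_s`` (−3…0 s before the trigger), and the window value is
    (F − F0)/F0. Events whose window or baseline would cross a recording
    edge are dropped and counted in ``n_dropped``.
    """
    pre_f, post_f = event_window_frames(window_s, stack.frame_rate_hz)
    b_lo, b_hi = event_window_frames(baseline_s, stack.frame_rate_hz)
    lo = min(pre_f, b_lo)
    triggers, n_dropped = _valid_triggers(trigger_frames, stack.n_frames, lo, post_f)
    if triggers.size == 0:
        raise ValueError("no surviving events: every window crosses a recording edge")
    T_win = post_f - pre_f
    H, W = stack.frame_shape
    out = np.empty((triggers.size, T_win, H, W), dtype=np.float32)
    for i, f in enumerate(triggers):
        f0 = stack.data[f + b_lo:f + b_hi].mean(axis=0, dtype=np.float64)
        bad = f0 == 0
        if bad.any():
            rows, cols = np.nonzero(bad)
            raise ValueError(
                f"zero baseline F0 at pixels {list(zip(rows[:5].tolist(), cols[:5].tolist()))}"
                + ("..." if rows.size > 5 else ""))
        win = stack.data[f + pre_f:f + post_f].astype(np.float64)
        out[i] = ((win - f0) / f0).astype(np.float32)
    if n_dropped:
        logger.info("dff_event: dropped %d events with clipped windows", n_dropped)
    return EventTensor(values=out, window_s=window_s, trigger_frames=triggers,
                       frame_rate_hz=stack.frame_rate_hz, n_dropped=n_dropped)


def dff_global(stack: ImagingStack) -> ImagingStack:
    """ΔF/F0 with the per-pixel baseline taken as the mean over the whole
    recording."""
    f0 = stack.data.mean(axis=0, dtype=np.float64)
    if np.any(f0 == 0):
        rows, cols = np.nonzero(f0 == 0)
        raise ValueError(f"zero global baseline at pixels {list(zip(rows[:5], cols[:5]))}")
    dff = (stack.data.astype(np.float64) - f0) / f0
    return stack.with_data(dff.astype(np.float32))


def bandpass(data: np.ndarray | ImagingStack, low_hz: float, high_hz: float,
             fs: float | None = None, order: int = 4):
    """Zero-phase Butterworth band-pass along the time axis.

    Accepts a 1-D trace, a T x ... array or an :class:`ImagingStack`
    (``fs`` taken from the stack). DC is rejected (> 40 dB down at 0 Hz).
    """
    if isinstance(data, ImagingStack):
        out = bandpass(data.data, low_hz, high_hz, fs=data.frame_rate_hz, order=order)
        return data.with_data(out)
    if fs is None:
        raise ValueError("fs required for array input")
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(f"band ({low_hz}, {high_hz}) outside (0, Nyquist={fs / 2})")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=np.float64), axis=0)


def regress_global_signal(stack: ImagingStack, mode: str = "regress") -> ImagingStack:
    """Remove the global (mask-mean) time course from every pixel.

    ``regress`` subtracts beta * g(t) per pixel with beta the least-squares
    coefficient against the mean-removed global trace g; ``subtract``
    removes g directly (beta = 1). The stack should already be ΔF/F0.
    """
    mask = stack.brain_mask
    if mask is None:
        mask = np.ones(stack.frame_shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    T = stack.n_frames
    data = stack.data.reshape(T, -1).astype(np.float64)
    g = data[:, mask.ravel()].mean(axis=1)
    g = g - g.mean()
    denom = float(g @ g)
    if mode == "subtract" or denom == 0.0:
        out = data - g[:, None]
    elif mode == "regress":
        beta = (g @ data) / denom  # per-pixel LS coefficient
        out = data - np.outer(g, beta)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return stack.with_data(out.reshape(stack.data.shape).astype(np.float32))


def hemodynamic_correct(green: ImagingStack, blue_reflect: ImagingStack) -> ImagingStack:
    """Ratiometric common-mode correction.

    Divides the green fractional signal F_g/F0_g by the reflectance
    fraction F_b/F0_b (baselines = whole-recording means) and reports the
    result as corrected ΔF/F0 = ratio − 1. A purely multiplicative signal
    shared by both channels cancels exactly.
    """
    if green.data.shape != blue_reflect.data.shape:
        raise ValueError("green and blue stacks must share T x H x W")
    f0_g = green.data.mean(axis=0, dtype=np.float64)
    f0_b = blue_reflect.data.mean(axis=0, dtype=np.float64)
    if np.any(f0_b == 0):
        raise ValueError("zero blue baseline")
    if np.any(f0_g == 0):
        raise ValueError("zero green baseline")
    ratio = (green.data / f0_g) / (blue_reflect.data / f0_b)
    return green.with_data((ratio - 1.0).astype(np.float32))


def estimate_ar_coeffs(trace: np.ndarray, order: int = 1) -> np.ndarray:
    """Estimate AR(p) coefficients from the autocovariance (Yule-Walker)."""
    x = np.asarray(trace, dtype=np.float64)
    x = x - x.mean()
    n = x.size
    if order not in (1, 2):
        raise ValueError("AR order must be 1 or 2")
    acov = np.array([x[: n - k] @ x[k:] for k in range(order + 1)]) / n
    if acov[0] == 0:
        return np.zeros(order)
    import scipy.linalg as sla

    R = sla.toeplitz(acov[:order])
    return np.linalg.solve(R, acov[1: order + 1])


def deconvolve(trace: np.ndarray, ar_coeffs: np.ndarray | str = "auto",
               nonneg: bool = True) -> tuple[np.ndarray, float]:
    """Invert an autoregressive calcium-transient kernel to recover the
    underlying activity.

    The calcium trace is modelled as c_t = sum_i g_i c_{t-i} + s_t with
    s_t >= 0 the per-frame activity; applying the AR filter (1 − g_1 B −
    … − g_p B^p) to the trace yields s. With ``nonneg`` the result is
    clipped at zero. Returns (activity, reconstruction_residual) where the
    residual is the RMS difference between the reconvolved activity and the
    input (zero when clipping removed nothing).
    """
    x = np.asarray(trace, dtype=np.float64)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("trace must be nonempty and finite")
    if isinstance(ar_coeffs, str):
        if ar_coeffs != "auto":
            raise ValueError("ar_coeffs must be an array or 'auto'")
        g = estimate_ar_coeffs(x, order=1)
    else:
        g = np.asarray(ar_coeffs, dtype=np.float64).ravel()
    # stability: roots of 1 - g1 z^-1 - ... must lie inside the unit circle
    roots = np.roots(np.concatenate([[1.0], -g])) if g.size else np.array([])
    if np.any(np.abs(roots) >= 1.0):
        raise ValueError(f"unstable AR coefficients {g}: root magnitudes {np.abs(roots)}")
    s = signal.lfilter(np.concatenate([[1.0], -g]), [1.0], x)
    if nonneg:
        s = np.maximum(s, 0.0)
    recon = signal.lfilter([1.0], np.concatenate([[1.0], -g]), s)
    residual = float(np.sqrt(np.mean((recon - x) ** 2)))
    return s, residual


def roi_power_spectrum(traces: np.ndarray, frame_rate_hz: float) -> dict[str, np.ndarray]:
    """One-sided amplitude spectrum of one trace or a bank of traces.

    ``traces`` is T or n x T. Returns frequency bins, the mean amplitude
    spectrum and its SEM across traces (SEM zero for a single trace).
    """
    x = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    if x.shape[1] < 2:
        raise ValueError("need T >= 2 samples")
    n = x.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate_hz)
    amp = np.abs(np.fft.rfft(x, axis=1)) / n
    amp[:, 1:] *= 2.0  # fold negative frequencies
    if n % 2 == 0:
        amp[:, -1] /= 2.0  # Nyquist bin is not doubled
    mean = amp.mean(axis=0)
    sem = amp.std(axis=0, ddof=1) / np.sqrt(x.shape[0]) if x.shape[0] > 1 else np.zeros_like(mean)
    return {"frequency_hz": freqs, "amplitude": mean, "sem": sem}
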