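"""Event-stream computations: robust threshold detection, unit inclusion
filters, ISI spiking-mode quadrants, burst-first selection, MUA pooling and
LFP band amplitudes."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import SpikeTrain

logger = logging.getLogger("mesomap")

__all__ = [
    "UnitFilterCriteria",
    "SpikingModeLabels",
    "robust_sigma",
    "robust_threshold",
    "detect_events",
    "filter_units",
    "isi_quadrants",
    "burst_first_spikes",
    "mua_pool",
    "lfp_frame_amplitude",
    "LFP_BANDS",
]

#: Conventional LFP frequency bands (Hz).
LFP_BANDS = {"delta": (0.1, 4.0), "theta": (4.0, 8.0), "gamma": (25.0, 100.0)}

#: Quantile constant relating median absolute deviation to Gaussian sigma.
MAD_SCALE = 0.6745


@dataclass
class UnitFilterCriteria:
    """Inclusion thresholds for single units: peak-to-peak amplitude of at
    least 40 µV, at least 200 spikes, and a cortical calcium response
    (peak |STMTD|) of at least 0.5%."""

    min_amplitude_uv: float = 40.0
    min_spikes: int = 200
    min_stmtd_pct: float = 0.5

    def __post_init__(self) -> None:
        if min(self.min_amplitude_uv, self.min_spikes, self.min_stmtd_pct) < 0:
            raise ValueError("criteria must be >= 0")


@dataclass
class SpikingModeLabels:
    """Per-spike firing-mode labels from the (ISI_prev, ISI_next) quadrants."""

    labels: list[str]
    isi_prev: np.ndarray
    isi_next: np.ndarray
    boundary_s: float

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


def robust_sigma(trace: np.ndarray) -> float:
    """Robust noise SD estimate: median(|x|) / 0.6745.

    For zero-mean Gaussian noise median(|x|) = 0.6745 sigma, so the ratio
    recovers sigma while staying insensitive to a small fraction of large
    spikes riding on the noise.
    """
    x = np.asarray(trace, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty trace")
    return float(np.median(np.abs(x)) / MAD_SCALE)


def robust_threshold(highpass_trace: np.ndarray, k: float = 4.5) -> float:
    """Detection threshold k x robust sigma of a high-pass trace.

    k = 4.5 for single-unit detection; multi-unit pooling uses k = 4.
    """
    return k * robust_sigma(highpass_trace)


def detect_events(highpass_trace: np.ndarray, fs: float, threshold: float,
                  refractory_ms: float = 1.0, polarity: str = "negative") -> np.ndarray:
    """Times (s) of threshold-crossing extrema in a high-pass trace.

    Local extrema whose magnitude exceeds ``threshold`` and that are
    separated by at least the refractory period are kept; ``polarity``
    selects negative-going troughs (default for extracellular spikes),
    positive peaks, or ``both``.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    x = np.asarray(highpass_trace, dtype=np.float64)
    if polarity == "negative":
        y = -x
    elif polarity == "positive":
        y = x
    elif polarity == "both":
        y = np.abs(x)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    distance = max(1, int(round(refractory_ms * 1e-3 * fs)))
    peaks, _ = signal.find_peaks(y, height=threshold, distance=distance)
    return peaks / fs


def filter_units(units: list[SpikeTrain],
                 criteria: UnitFilterCriteria,
                 stmtd_peaks_pct: dict[str, float]) -> tuple[list[SpikeTrain], list[dict]]:
    """Apply the unit-inclusion filters.

    A unit is retained iff amplitude >= 40 µV AND n_spikes >= 200 AND
    max |STMTD| >= 0.5% (boundaries inclusive). Units missing amplitude or
    an STMTD measurement are rejected with reason ``unmeasured``. Returns
    (retained units, rejection log).
    """
    kept: list[SpikeTrain] = []
    rejected: list[dict] = []
    for u in units:
        peak_pct = stmtd_peaks_pct.get(u.unit_id)
        if u.peak_to_peak_uv is None or peak_pct is None:
            rejected.append({"unit_id": u.unit_id, "reason": "unmeasured"})
            continue
        if u.peak_to_peak_uv < criteria.min_amplitude_uv:
            rejected.append({"unit_id": u.unit_id, "reason": "amplitude",
                             "value": u.peak_to_peak_uv})
        elif u.n_spikes < criteria.min_spikes:
            rejected.append({"unit_id": u.unit_id, "reason": "spike_count",
                             "value": u.n_spikes})
        elif abs(peak_pct) < criteria.min_stmtd_pct:
            rejected.append({"unit_id": u.unit_id, "reason": "stmtd",
                             "value": peak_pct})
        else:
            kept.append(u)
    return kept, rejected


def isi_quadrants(train: SpikeTrain, boundary_s: float = 0.1) -> SpikingModeLabels:
    """Label each spike by its (previous, next) inter-spike-interval quadrant.

    With the quadrant boundary at ``boundary_s`` (log axes in the usual
    scatter display): (long prev, short next) = first spike of a burst;
    (short, short) = inside a burst; (short, long) = last spike of a burst;
    (long, long) = tonic. The first and last spike of the record have an
    undefined neighbor treated as +inf (long).
    """
    if train.n_spikes < 3:
        raise ValueError("need at least 3 spikes to define ISI quadrants")
    t = train.times_s
    isi = np.diff(t)
    isi_prev = np.concatenate([[np.inf], isi])
    isi_next = np.concatenate([isi, [np.inf]])
    labels = []
    for p, nx in zip(isi_prev, isi_next):
        short_p, short_n = p <= boundary_s, nx <= boundary_s
        if not short_p and short_n:
            labels.append("first_in_burst")
        elif short_p and short_n:
            labels.append("in_burst")
        elif short_p and not short_n:
            labels.append("last_in_burst")
        else:
            labels.append("tonic")
    return SpikingModeLabels(labels=labels, isi_prev=isi_prev, isi_next=isi_next,
                             boundary_s=boundary_s)


def burst_first_spikes(train: SpikeTrain, silence_s: float = 0.5) -> SpikeTrain:
    """Spikes preceded by more than ``silence_s`` of silence.

    The first spike of the record is always included (ISI_prev = +inf).
    With ``silence_s = 0`` every spike qualifies.
    """
    t = train.times_s
    isi_prev = np.concatenate([[np.inf], np.diff(t)])
    keep = isi_prev > silence_s
    return train.subset(np.where(keep)[0], suffix=f"silence>{silence_s:g}s")


def mua_pool(channel_traces: list[np.ndarray], fs: float, k: float = 4.0,
             refractory_ms: float = 1.0, polarity: str = "negative") -> np.ndarray:
    """Merged multi-unit event times across channels.

    Each channel is thresholded at k = 4 robust sigmas (no unit isolation)
    and the detected times are pooled and sorted. Duplicate events from
    redundant channels are retained.
    """
    if not channel_traces:
        raise ValueError("need at least one channel")
    all_times = []
    for ch in channel_traces:
        thr = robust_threshold(ch, k=k)
        if thr == 0:
            continue
        all_times.append(detect_events(ch, fs, thr, refractory_ms, polarity))
    if not all_times:
        return np.array([])
    return np.sort(np.concatenate(all_times))


def lfp_frame_amplitude(lfp_trace: np.ndarray, lfp_fs: float,
                        band: tuple[float, float] | str,
                        frame_times: np.ndarray) -> np.ndarray:
    """Average band-limited LFP value inside each imaging-frame interval.

    ``band`` is (low, high) in Hz or one of the named bands (delta 0.1–4,
    theta 4–8, gamma 25–100 Hz). ``frame_times`` holds the start time of
    every imaging frame; each weight is the mean of the band-passed LFP
    over [start_i, start_{i+1}). Returns one weight per frame.
    """
    if isinstance(band, str):
        band = LFP_BANDS[band]
    low, high = band
    if not (0 < low < high < lfp_fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={lfp_fs / 2})")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=lfp_fs, output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(lfp_trace, dtype=np.float64))
    frame_times = np.asarray(frame_times, dtype=np.float64)
    n_frames = frame_times.size
    dt = np.median(np.diff(frame_times)) if n_frames > 1 else filt.size / lfp_fs
    edges = np.concatenate([frame_times, [frame_times[-1] + dt]])
    sample_t = np.arange(filt.size) / lfp_fs
    idx = np.searchsorted(edges, sample_t, side="right") - 1
    weights = np.zeros(n_frames)
    valid = (idx >= 0) & (idx < n_frames)
    counts = np.bincount(idx[valid], minlength=n_frames)
    sums = np.bincount(idx[valid], weights=filt[valid], minlength=n_frames)
    nonzero = counts > 0
    weights[nonzero] = sums[nonzero] / counts[nonzero]
    return weights
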