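"""Movement quantification from a behavior camera, quiescence
segmentation, and quiet-restricted event-triggered mapping.

Movement is summarised as a per-frame gradient density (mean absolute
frame-to-frame difference inside a face/forepaw ROI), smoothed at 0.1 Hz.
Epochs are thresholded relative to the profile's median and SD: quiet
below median + sigma/10, movement above median + sigma. Quiet epochs are
trimmed by 10 s at both ends and kept only if more than 10 s survive, so a
quiet spike set is well isolated from any movement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import ImagingStack, SpikeTrain, times_to_frames
from .netmatch import map_similarity
from .stamap import stm_from_stack

logger = logging.getLogger("mesomap")

__all__ = [
    "IntervalSet",
    "movement_density",
    "segment_quiescence",
    "spikes_in_intervals",
    "quiet_restricted_sta",
]


@dataclass
class IntervalSet:
    """Non-overlapping, sorted (start_s, end_s) intervals with a label."""

    intervals: list[tuple[float, float]]
    label: str = "quiet"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in self.intervals:
            if a >= b:
                raise ValueError(f"degenerate interval ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(self.intervals, self.intervals[1:]):
            if a2 < b1:
                raise ValueError("intervals must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.intervals)

    def total_s(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def contains(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=np.float64)
        inside = np.zeros(times.shape, dtype=bool)
        for a, b in self.intervals:
            inside |= (times >= a) & (times < b)
        return inside


def movement_density(video: ImagingStack, roi_mask: np.ndarray | None = None,
                     reduce: str = "mean") -> np.ndarray:
    """Per-frame movement density from a behavior video.

    d(t) = sum (or mean, default) over ROI pixels of |F_t − F_{t−1}|.
    d(0) is set equal to d(1) so the trace has one value per frame.
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames")
    mask = np.ones(video.frame_shape, bool) if roi_mask is None else np.asarray(roi_mask, bool)
    if not mask.any():
        raise ValueError("empty ROI")
    flat = video.data.reshape(video.n_frames, -1)[:, mask.ravel()].astype(np.float64)
    grad = np.abs(np.diff(flat, axis=0))
    if reduce == "mean":
        d = grad.mean(axis=1)
    elif reduce == "sum":
        d = grad.sum(axis=1)
    else:
        raise ValueError(f"unknown reduce {reduce!r}")
    return np.concatenate([[d[0]], d])


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def segment_quiescence(density: np.ndarray, fs: float,
                       smooth_hz: float = 0.1,
                       trim_s: float = 10.0,
                       min_quiet_s: float = 10.0) -> tuple[IntervalSet, IntervalSet]:
    """Quiet and movement epochs from a movement-density trace.

    The density is zero-phase low-passed at ``smooth_hz``; with median and
    sigma of the smoothed profile, quiet = runs below median + sigma/10 and
    movement = runs above median + sigma. Each quiet run is trimmed by
    ``trim_s`` at both ends and kept only if longer than ``min_quiet_s``
    afterwards; movement runs are reported untrimmed. Thresholds are
    relative, so the segmentation is invariant to affine rescaling of the
    density.
    """
    d = np.asarray(density, dtype=np.float64)
    duration = d.size / fs
    if duration <= 2 * trim_s + min_quiet_s:
        logger.warning("record of %.1f s too short for %g s trims + %g s minimum",
                       duration, trim_s, min_quiet_s)
        return (IntervalSet([], "quiet"), IntervalSet([], "movement"))
    if smooth_hz and 0 < smooth_hz < fs / 2:
        sos = signal.butter(2, smooth_hz, btype="low", fs=fs, output="sos")
        smooth = signal.sosfiltfilt(sos, d)
    else:
        smooth = d
    med = float(np.median(smooth))
    sigma = float(np.std(smooth))
    params = {"median": med, "sigma": sigma, "smooth_hz": smooth_hz,
              "trim_s": trim_s, "min_quiet_s": min_quiet_s}
    # <= plus a relative epsilon so a constant profile (sigma = 0 up to
    # filter round-off) counts as quiet everywhere
    eps = 1e-9 * max(1.0, abs(med))
    quiet_runs = _runs_above(smooth <= med + sigma / 10.0 + eps)
    move_runs = _runs_above(smooth > med + sigma + eps)
    quiet = []
    for a, b in quiet_runs:
        start, end = a / fs + trim_s, b / fs - trim_s
        if end - start > min_quiet_s:
            quiet.append((start, end))
    movement = [(a / fs, b / fs) for a, b in move_runs]
    return (IntervalSet(quiet, "quiet", params), IntervalSet(movement, "movement", params))


def spikes_in_intervals(train: SpikeTrain, intervals: IntervalSet) -> SpikeTrain:
    keep = intervals.contains(train.times_s)
    return train.subset(np.where(keep)[0], suffix=intervals.label)


def quiet_restricted_sta(stack: ImagingStack, train: SpikeTrain,
                         quiet: IntervalSet,
                         window_s: tuple[float, float] = (-3.0, 3.0),
                         peak_window_s: tuple[float, float] = (-1.0, 1.0),
                         mask: np.ndarray | None = None) -> dict:
    """STM from all spikes versus spikes restricted to quiet epochs.

    Returns both maps, their Pearson r, the two peak amplitudes and the
    spike counts; no statistical claim is made — the report is the
    comparison the reader judges.
    """
    quiet_train = spikes_in_intervals(train, quiet)
    if quiet_train.n_spikes == 0:
        raise ValueError("no spikes inside quiet intervals")
    frames_all, _ = times_to_frames(train.times_s, stack.frame_rate_hz, stack.n_frames)
    frames_q, _ = times_to_frames(quiet_train.times_s, stack.frame_rate_hz, stack.n_frames)
    stm_all = stm_from_stack(stack, frames_all, window_s, peak_window_s)
    stm_quiet = stm_from_stack(stack, frames_q, window_s, peak_window_s)
    return {
        "stm_all": stm_all,
        "stm_quiet": stm_quiet,
        "r": map_similarity(stm_all.map, stm_quiet.map, mask),
        "peak_all": float(stm_all.map.ravel()[np.abs(stm_all.map).argmax()]),
        "peak_quiet": float(stm_quiet.map.ravel()[np.abs(stm_quiet.map).argmax()]),
        "n_all": train.n_spikes,
        "n_quiet": quiet_train.n_spikes,
    }
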