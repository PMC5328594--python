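"""Event-triggered averaging: STA movies, static peak maps (STM),
random-trigger controls, spike-triggered variance maps and LFP-weighted
frame averages.

The STA movie is the frame-by-frame mean of event-aligned ΔF/F0 windows
(−3…+3 s); the STM is the per-pixel peak of that movie within ±1 s of the
trigger. The default peak is the signed extremum (the value of largest
absolute magnitude, sign retained) so that depressed regions map as
negative; a literal ``max`` mode is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ImagingStack
from .preprocess import EventTensor, event_window_frames

__all__ = [
    "StaMovie",
    "STM",
    "sta_sequence",
    "sta_movie",
    "stm_peak_map",
    "stm_from_stack",
    "random_control",
    "stv_map",
    "weighted_frame_map",
]


@dataclass
class StaMovie:
    """T_win x H x W mean ΔF/F0 movie around a set of triggers."""

    values: np.ndarray
    n_events_used: int
    window_s: tuple[float, float]
    frame_rate_hz: float
    trigger_source: str = "unit"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("StaMovie values must be T_win x H x W")
        if self.n_events_used < 1:
            raise ValueError("n_events_used must be >= 1")

    @property
    def window_times(self) -> np.ndarray:
        pre, _ = self.window_s
        offset = int(round(pre * self.frame_rate_hz))
        return (np.arange(self.values.shape[0]) + offset) / self.frame_rate_hz


@dataclass
class STM:
    """Static per-pixel peak map of an STA movie within a peak window."""

    map: np.ndarray
    peak_window_s: tuple[float, float] = (-1.0, 1.0)
    peak_time_map: np.ndarray | None = None
    mode: str = "signed_extremum"
    n_events_used: int = 1

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.float64)
        if not np.all(np.isfinite(self.map)):
            raise ValueError("STM map must be finite")


def sta_sequence(events: EventTensor, trigger_source: str = "unit") -> StaMovie:
    """Frame-wise mean across the events of an :class:`EventTensor`."""
    if events.n_events < 1:
        raise ValueError("empty event tensor")
    mean = events.values.mean(axis=0, dtype=np.float64)
    return StaMovie(values=mean, n_events_used=events.n_events,
                    window_s=events.window_s, frame_rate_hz=events.frame_rate_hz,
                    trigger_source=trigger_source, n_dropped=events.n_dropped)


def sta_movie(stack: ImagingStack, trigger_frames: np.ndarray,
              window_s: tuple[float, float] = (-3.0, 3.0),
              baseline_s: tuple[float, float] = (-3.0, 0.0),
              trigger_source: str = "unit") -> StaMovie:
    """STA movie computed by streaming over events, never materialising the
    full event tensor.

    Numerically identical to ``sta_sequence(dff_event(...))`` but with a
    memory footprint of one window, which makes whole-session subsampling
    analyses practical.
    """
    pre_f, post_f = event_window_frames(window_s, stack.frame_rate_hz)
    b_lo, b_hi = event_window_frames(baseline_s, stack.frame_rate_hz)
    lo = min(pre_f, b_lo)
    triggers = np.asarray(trigger_frames, dtype=np.int64)
    keep = (triggers + lo >= 0) & (triggers + post_f <= stack.n_frames)
    n_dropped = int((~keep).sum())
    triggers = triggers[keep]
    if triggers.size == 0:
        raise ValueError("no surviving events: every window crosses a recording edge")
    acc = np.zeros((post_f - pre_f,) + stack.frame_shape, dtype=np.float64)
    for f in triggers:
        f0 = stack.data[f + b_lo:f + b_hi].mean(axis=0, dtype=np.float64)
        if np.any(f0 == 0):
            raise ValueError("zero baseline F0 under an event window")
        acc += (stack.data[f + pre_f:f + post_f].astype(np.float64) - f0) / f0
    acc /= triggers.size
    return StaMovie(values=acc, n_events_used=int(triggers.size), window_s=window_s,
                    frame_rate_hz=stack.frame_rate_hz, trigger_source=trigger_source,
                    n_dropped=n_dropped)


def _peak_window_slice(movie: StaMovie, peak_window_s: tuple[float, float]) -> slice:
    times = movie.window_times
    lo, hi = peak_window_s
    inside = np.where((times >= lo) & (times <= hi))[0]
    if inside.size == 0:
        raise ValueError(f"peak window {peak_window_s} empty within movie window "
                         f"{movie.window_s}")
    return slice(int(inside[0]), int(inside[-1]) + 1)


def stm_peak_map(movie: StaMovie, peak_window_s: tuple[float, float] = (-1.0, 1.0),
                 mode: str = "signed_extremum") -> STM:
    """Per-pixel peak of the STA movie within ``peak_window_s``.

    ``signed_extremum`` (default) returns the value of largest magnitude
    with its sign, so depression maps negative; ``max`` returns the literal
    per-pixel maximum.
    """
    sl = _peak_window_slice(movie, peak_window_s)
    win = movie.values[sl]
    times = movie.window_times[sl]
    if mode == "signed_extremum":
        idx = np.abs(win).argmax(axis=0)
    elif mode == "max":
        idx = win.argmax(axis=0)
    else:
        raise ValueError(f"unknown peak mode {mode!r}")
    rows, cols = np.indices(idx.shape)
    peak = win[idx, rows, cols]
    peak_time = times[idx]
    return STM(map=peak, peak_window_s=peak_window_s, peak_time_map=peak_time,
               mode=mode, n_events_used=movie.n_events_used)


def stm_from_stack(stack: ImagingStack, trigger_frames: np.ndarray,
                   window_s: tuple[float, float] = (-3.0, 3.0),
                   peak_window_s: tuple[float, float] = (-1.0, 1.0),
                   mode: str = "signed_extremum",
                   trigger_source: str = "unit") -> STM:
    """Convenience composition: streamed STA movie, then peak map."""
    movie = sta_movie(stack, trigger_frames, window_s, trigger_source=trigger_source)
    return stm_peak_map(movie, peak_window_s, mode=mode)


def random_control(stack: ImagingStack, n_events: int,
                   window_s: tuple[float, float] = (-3.0, 3.0),
                   peak_window_s: tuple[float, float] = (-1.0, 1.0),
                   seed: int = 0, n_repeats: int = 10,
                   mode: str = "signed_extremum") -> dict:
    """Random-trigger control STMs.

    Draws ``n_events`` triggers uniformly over the frames whose windows fit
    inside the recording, ``n_repeats`` times, and returns the per-repeat
    STMs together with their pixelwise mean and SD envelope. Against these
    the real-trigger STM peak can be judged.
    """
    pre_f, post_f = event_window_frames(window_s, stack.frame_rate_hz)
    # the default -3..0 s baseline never reaches further back than the window
    first, last = max(0, -pre_f), stack.n_frames - post_f
    if last <= first:
        raise ValueError("recording too short for the requested window")
    if n_events > last - first:
        raise ValueError(f"n_events={n_events} exceeds the {last - first} valid frames")
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n_repeats):
        triggers = rng.choice(np.arange(first, last), size=n_events, replace=False)
        stm = stm_from_stack(stack, triggers, window_s, peak_window_s, mode=mode,
                             trigger_source="random")
        maps.append(stm.map)
    maps = np.stack(maps)
    return {
        "stms": maps,
        "mean": maps.mean(axis=0),
        "sd": maps.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros_like(maps[0]),
        "n_repeats": n_repeats,
        "n_events": n_events,
        "seed": seed,
    }


def stv_map(events: EventTensor, peak_window_s: tuple[float, float] = (-1.0, 1.0),
            baseline_s: tuple[float, float] = (-3.0, 0.0)) -> STM:
    """Spike-triggered variance map.

    Across-event per-pixel/frame variance, referenced to the mean
    pre-trigger (−3…0 s) variance of the same pixel, then reduced to the
    per-pixel extremum inside the peak window.
    """
    if events.n_events < 2:
        raise ValueError("need >= 2 events for a variance map")
    var = events.values.astype(np.float64).var(axis=0, ddof=0)  # T_win x H x W
    times = events.window_times
    b_lo, b_hi = baseline_s
    base = var[(times >= b_lo) & (times < b_hi)].mean(axis=0)
    rel = var - base
    lo, hi = peak_window_s
    win = rel[(times >= lo) & (times <= hi)]
    idx = np.abs(win).argmax(axis=0)
    rows, cols = np.indices(idx.shape)
    return STM(map=win[idx, rows, cols], peak_window_s=peak_window_s,
               mode="signed_extremum", n_events_used=events.n_events)


def weighted_frame_map(stack_dff: ImagingStack | np.ndarray, weights: np.ndarray,
                       normalization: str = "abs") -> np.ndarray:
    """Weighted average image: map(x) = sum_t w_t F_t(x) / N.

    The normaliser N is sum|w_t| (default ``abs``, so positive and negative
    weight phases cannot cancel the scale), sum of positive weights
    (``positive``), or plain sum (``sum``). Frames with large positive
    weights dominate; frames with near-zero weights contribute little.
    """
    data = stack_dff.data if isinstance(stack_dff, ImagingStack) else np.asarray(stack_dff)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.ndim != 1 or weights.size != data.shape[0]:
        raise ValueError("weights must be one per frame")
    if np.all(weights == 0):
        raise ValueError("all-zero weights")
    num = np.tensordot(weights, data.astype(np.float64), axes=(0, 0))
    if normalization == "abs":
        denom = np.abs(weights).sum()
    elif normalization == "positive":
        denom = np.maximum(weights, 0.0).sum()
    elif normalization == "sum":
        denom = weights.sum()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0:
        raise ValueError(f"normalization {normalization!r} has zero denominator")
    return num / denom
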