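"""Map reliability: spike-count subsampling curves, split-half maps,
minimum-spike estimation, FWHM contours and pairwise contour overlap.

Reliability is expressed as the Pearson r between pairs of STMs built from
disjoint random subsets of one unit's spikes: the r-versus-count curve
rises toward 1 as averaging defeats single-event variability, and the
smallest count whose median r clears a threshold (0.9 by default) is the
unit's minimum stable spike count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ImagingStack, SpikeTrain, times_to_frames
from .netmatch import map_similarity
from .stamap import stm_from_stack

__all__ = [
    "StabilityCurve",
    "ContourMask",
    "default_sizes",
    "subsample_curve",
    "split_half_maps",
    "min_spikes_for_stability",
    "fwhm_contour",
    "overlap_percent",
]


@dataclass
class StabilityCurve:
    """Between-subset STM correlations as a function of spike count."""

    sizes: list[int]
    r_values: dict[int, list[float]]
    n_pairs: int
    seed: int

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        for size, rs in self.r_values.items():
            if any(abs(r) > 1 + 1e-9 for r in rs):
                raise ValueError(f"r outside [-1, 1] at size {size}")

    def median_r(self) -> dict[int, float]:
        return {s: float(np.median(rs)) for s, rs in self.r_values.items() if rs}


@dataclass
class ContourMask:
    """Pixels at or beyond half of a map's extremal value."""

    mask: np.ndarray
    level: float
    polarity: str  # positive | negative

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def default_sizes(n_spikes: int, start: int = 2) -> list[int]:
    """Doubling spike-count ladder 2, 4, ..., capped so disjoint pairs fit."""
    sizes = []
    s = start
    while 2 * s <= n_spikes and s <= 2048:
        sizes.append(s)
        s *= 2
    return sizes


def subsample_curve(stack: ImagingStack, train: SpikeTrain,
                    sizes: list[int] | None = None, n_pairs: int = 3,
                    seed: int = 0, window_s: tuple[float, float] = (-3.0, 3.0),
                    peak_window_s: tuple[float, float] = (-1.0, 1.0),
                    mode: str = "signed_extremum",
                    mask: np.ndarray | None = None) -> StabilityCurve:
    """Consistency of mapping versus spike count.

    For each size, ``n_pairs`` pairs of disjoint random spike subsets are
    drawn without replacement, an STM is built from each member, and the
    Pearson r between the pair is recorded.
    """
    if sizes is None:
        sizes = default_sizes(train.n_spikes)
    if not sizes:
        raise ValueError("no feasible sizes for this spike count")
    if max(sizes) * 2 > train.n_spikes:
        raise ValueError(f"size {max(sizes)} needs {2 * max(sizes)} spikes, "
                         f"unit has {train.n_spikes}")
    rng = np.random.default_rng(seed)
    frames_all, _ = times_to_frames(train.times_s, stack.frame_rate_hz, stack.n_frames)
    r_values: dict[int, list[float]] = {s: [] for s in sizes}
    for size in sizes:
        for _ in range(n_pairs):
            pick = rng.choice(frames_all.size, size=2 * size, replace=False)
            m1 = stm_from_stack(stack, frames_all[pick[:size]], window_s,
                                peak_window_s, mode=mode)
            m2 = stm_from_stack(stack, frames_all[pick[size:]], window_s,
                                peak_window_s, mode=mode)
            r_values[size].append(map_similarity(m1.map, m2.map, mask))
    return StabilityCurve(sizes=list(sizes), r_values=r_values, n_pairs=n_pairs,
                          seed=seed)


def split_half_maps(stack: ImagingStack, train: SpikeTrain,
                    scheme: str = "halves",
                    window_s: tuple[float, float] = (-3.0, 3.0),
                    peak_window_s: tuple[float, float] = (-1.0, 1.0),
                    mode: str = "signed_extremum",
                    mask: np.ndarray | None = None) -> dict:
    """Two STMs from complementary halves of a unit's spikes, plus their r.

    ``halves`` splits at the temporal midpoint of the spike list;
    ``odd_even`` alternates spikes. The two groups always partition the
    train.
    """
    if train.n_spikes < 4:
        raise ValueError("need >= 4 spikes for a split-half comparison")
    n = train.n_spikes
    idx = np.arange(n)
    if scheme == "halves":
        g1, g2 = idx[: n // 2], idx[n // 2:]
    elif scheme == "odd_even":
        g1, g2 = idx[::2], idx[1::2]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    frames, _ = times_to_frames(train.times_s, stack.frame_rate_hz, stack.n_frames)
    m1 = stm_from_stack(stack, frames[g1], window_s, peak_window_s, mode=mode)
    m2 = stm_from_stack(stack, frames[g2], window_s, peak_window_s, mode=mode)
    return {"stm1": m1, "stm2": m2,
            "r": map_similarity(m1.map, m2.map, mask), "scheme": scheme,
            "groups": (g1, g2)}


def min_spikes_for_stability(curve: StabilityCurve, r_threshold: float = 0.9) -> int | None:
    """Smallest spike count whose median between-subset r clears the
    threshold, or None when the curve never does."""
    med = curve.median_r()
    if not med:
        raise ValueError("empty stability curve")
    for size in curve.sizes:
        if size in med and med[size] >= r_threshold:
            return size
    return None


def fwhm_contour(stm_map: np.ndarray) -> ContourMask:
    """Full-width-half-max contour of a map.

    The half level is extremum/2 of the signed extremum; pixels at or
    beyond it (>= for a positive extremum, <= for a negative one) form the
    footprint. Flat maps have no contour.
    """
    m = np.asarray(stm_map, dtype=np.float64)
    ext = m.ravel()[np.abs(m).argmax()]
    if ext == 0:
        raise ValueError("flat zero map has no FWHM contour")
    level = ext / 2.0
    if ext > 0:
        mask = m >= level
        polarity = "positive"
    else:
        mask = m <= level
        polarity = "negative"
    return ContourMask(mask=mask, level=float(level), polarity=polarity)


def overlap_percent(mask_a: np.ndarray | ContourMask,
                    mask_b: np.ndarray | ContourMask) -> float:
    """Percentage overlap of two contour footprints.

    100 · |A ∩ B| / |A ∪ B| (Jaccard index × 100): symmetric, 0 for
    disjoint footprints and 100 only for identical ones.
    """
    a = mask_a.mask if isinstance(mask_a, ContourMask) else np.asarray(mask_a, bool)
    b = mask_b.mask if isinstance(mask_b, ContourMask) else np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    if not a.any() or not b.any():
        raise ValueError("empty mask")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(100.0 * inter / union)


def overlap_percent_min(mask_a: np.ndarray | ContourMask,
                        mask_b: np.ndarray | ContourMask) -> float:
    """Alternative overlap: 100 · |A ∩ B| / min(|A|, |B|)."""
    a = mask_a.mask if isinstance(mask_a, ContourMask) else np.asarray(mask_a, bool)
    b = mask_b.mask if isinstance(mask_b, ContourMask) else np.asarray(mask_b, bool)
    if not a.any() or not b.any():
        raise ValueError("empty mask")
    inter = np.logical_and(a, b).sum()
    return float(100.0 * inter / min(a.sum(), b.sum()))
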