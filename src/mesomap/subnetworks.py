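"""Single-event motif analysis: per-spike peak maps, partitioning into
sub-networks, matched spontaneous-motif subtraction.

Single-spike maps vary substantially because each spike occurs inside an
ongoing cortical state. Partitioning the flattened per-spike maps by
similarity (k-means in full pixel space) separates those states; grouping
the spontaneously occurring motifs against the same centers and
subtracting each partition's spontaneous mean from its spike-triggered
mean removes the state and leaves the unit's own component map in every
partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core_io import ImagingStack
from .netmatch import map_similarity
from .preprocess import event_window_frames

logger = logging.getLogger("mesomap")

__all__ = [
    "MotifSet",
    "single_event_motifs",
    "spontaneous_motifs",
    "partition_motifs",
    "assign_to_centers",
    "subnetwork_subtract",
]


@dataclass
class MotifSet:
    """Flattened per-event peak maps: n_motifs x (H·W)."""

    vectors: np.ndarray
    frame_shape: tuple[int, int]
    origin: str  # spike_triggered | spontaneous
    event_frames: np.ndarray
    labels: np.ndarray | None = None
    centers: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        H, W = self.frame_shape
        if self.vectors.ndim != 2 or self.vectors.shape[1] != H * W:
            raise ValueError("vectors must be n_motifs x (H*W)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.size != self.vectors.shape[0]:
                raise ValueError("one label per motif required")

    @property
    def n_motifs(self) -> int:
        return self.vectors.shape[0]

    def maps(self) -> np.ndarray:
        return self.vectors.reshape((-1,) + self.frame_shape)


def _event_peak_vector(stack: ImagingStack, f: int, pre_f: int, post_f: int,
                       b_lo: int, b_hi: int, p_lo: int, p_hi: int,
                       mode: str = "signed_extremum") -> np.ndarray:
    """Single-event ΔF/F0 peak map over the peak window."""
    f0 = stack.data[f + b_lo:f + b_hi].mean(axis=0, dtype=np.float64)
    if np.any(f0 == 0):
        raise ValueError("zero baseline under event window")
    win = (stack.data[f + p_lo:f + p_hi].astype(np.float64) - f0) / f0
    if mode == "max":
        return win.max(axis=0).ravel()
    if mode != "signed_extremum":
        raise ValueError(f"unknown peak mode {mode!r}")
    idx = np.abs(win).argmax(axis=0)
    rows, cols = np.indices(idx.shape)
    return win[idx, rows, cols].ravel()


def single_event_motifs(stack: ImagingStack, trigger_frames: np.ndarray,
                        window_s: tuple[float, float] = (-3.0, 3.0),
                        peak_window_s: tuple[float, float] = (-1.0, 1.0),
                        baseline_s: tuple[float, float] = (-3.0, 0.0),
                        mode: str = "signed_extremum") -> MotifSet:
    """Per-trigger single-event peak maps, flattened.

    Each motif is the per-pixel signed extremum of that one event's ΔF/F0
    window inside the ±1 s peak window — the n = 1 case of the STM
    definition. Events with clipped windows are dropped and counted.
    """
    pre_f, post_f = event_window_frames(window_s, stack.frame_rate_hz)
    b_lo, b_hi = event_window_frames(baseline_s, stack.frame_rate_hz)
    p_lo, p_hi = event_window_frames(peak_window_s, stack.frame_rate_hz)
    p_hi += 1  # inclusive upper edge, matching the movie peak-window slice
    lo = min(pre_f, b_lo)
    triggers = np.asarray(trigger_frames, dtype=np.int64)
    keep = (triggers + lo >= 0) & (triggers + max(post_f, p_hi) <= stack.n_frames)
    n_dropped = int((~keep).sum())
    triggers = triggers[keep]
    if triggers.size == 0:
        raise ValueError("no surviving events")
    vecs = np.empty((triggers.size, stack.frame_shape[0] * stack.frame_shape[1]))
    for i, f in enumerate(triggers):
        vecs[i] = _event_peak_vector(stack, int(f), pre_f, post_f, b_lo, b_hi,
                                     p_lo, p_hi, mode=mode)
    return MotifSet(vectors=vecs, frame_shape=stack.frame_shape,
                    origin="spike_triggered", event_frames=triggers,
                    n_dropped=n_dropped)


def spontaneous_motifs(stack: ImagingStack,
                       window_s: tuple[float, float] = (-3.0, 3.0),
                       peak_window_s: tuple[float, float] = (-1.0, 1.0),
                       baseline_s: tuple[float, float] = (-3.0, 0.0),
                       stride: int = 1,
                       exclude_frames: np.ndarray | None = None,
                       exclusion_radius: int = 0,
                       mode: str = "signed_extremum") -> MotifSet:
    """All possible motifs: every frame where the full window fits is a
    trigger (optionally strided).

    A stack of T frames and a window of W frames yields T − W + 1 motifs at
    stride 1. ``exclude_frames``/``exclusion_radius`` optionally drop
    triggers near known spikes for sensitivity analyses (off by default:
    spontaneous means *all* activity).
    """
    pre_f, post_f = event_window_frames(window_s, stack.frame_rate_hz)
    b_lo, b_hi = event_window_frames(baseline_s, stack.frame_rate_hz)
    lo = min(pre_f, b_lo)
    W_len = max(post_f, event_window_frames(peak_window_s, stack.frame_rate_hz)[1] + 1) - lo
    if stack.n_frames < W_len:
        raise ValueError("stack shorter than the motif window")
    first, last = -lo, stack.n_frames - (W_len + lo)
    triggers = np.arange(first, last + 1, stride, dtype=np.int64)
    if exclude_frames is not None and exclusion_radius > 0:
        bad = np.zeros(stack.n_frames, dtype=bool)
        for f in np.asarray(exclude_frames, dtype=np.int64):
            bad[max(0, f - exclusion_radius):f + exclusion_radius + 1] = True
        triggers = triggers[~bad[triggers]]
    ms = single_event_motifs(stack, triggers, window_s, peak_window_s, baseline_s,
                             mode=mode)
    ms.origin = "spontaneous"
    return ms


def partition_motifs(motifs: MotifSet, k: int = 4, seed: int = 0,
                     n_init: int = 10) -> MotifSet:
    """k-means partition of the motif vectors in full pixel space.

    Returns the same set with ``labels`` and ``centers`` filled in. PCA is
    useful only for display; distances here are Euclidean over all pixels.
    """
    if motifs.n_motifs < k:
        raise ValueError(f"need >= k={k} motifs, got {motifs.n_motifs}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(motifs.vectors)
    return MotifSet(vectors=motifs.vectors, frame_shape=motifs.frame_shape,
                    origin=motifs.origin, event_frames=motifs.event_frames,
                    labels=labels, centers=km.cluster_centers_.astype(np.float64),
                    n_dropped=motifs.n_dropped)


def assign_to_centers(motifs: MotifSet, centers: np.ndarray) -> MotifSet:
    """Nearest-center (Euclidean) assignment against existing centers.

    No re-fitting: this is how spontaneous motifs are grouped against the
    spike-generated sub-network centers. Ties go to the lower-index center.
    """
    centers = np.asarray(centers, dtype=np.float64)
    if centers.ndim != 2 or centers.shape[1] != motifs.vectors.shape[1]:
        raise ValueError("center dimension mismatch")
    d2 = ((motifs.vectors[:, None, :] - centers[None]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)  # argmin takes the first minimum: low-index tie-break
    return MotifSet(vectors=motifs.vectors, frame_shape=motifs.frame_shape,
                    origin=motifs.origin, event_frames=motifs.event_frames,
                    labels=labels, centers=centers, n_dropped=motifs.n_dropped)


def subnetwork_subtract(spike_set: MotifSet, spont_set: MotifSet,
                        reference_map: np.ndarray | None = None) -> dict:
    """Per-partition spontaneous subtraction.

    For each partition j, diff_j = mean(spike motifs in j) − mean(spont
    motifs in j); both sets must be labeled against the same centers.
    Reports, per partition, the spike/spont counts and (when a reference
    map such as the all-spike STM is given) the similarity r of the raw
    partition mean and of the difference map to the reference. Partitions
    empty on either side are skipped and listed.
    """
    if spike_set.labels is None or spont_set.labels is None:
        raise ValueError("both motif sets must be labeled (partition/assign first)")
    if spike_set.centers is None or spont_set.centers is None or \
            not np.array_equal(spike_set.centers, spont_set.centers):
        raise ValueError("motif sets must share the same centers")
    k = spike_set.centers.shape[0]
    H, W = spike_set.frame_shape
    diffs: dict[int, np.ndarray] = {}
    spike_means: dict[int, np.ndarray] = {}
    spont_means: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    report: dict[int, dict] = {}
    for j in range(k):
        sj = spike_set.vectors[spike_set.labels == j]
        pj = spont_set.vectors[spont_set.labels == j]
        if sj.shape[0] == 0 or pj.shape[0] == 0:
            skipped.append(j)
            logger.warning("subnetwork_subtract: partition %d empty on one side "
                           "(%d spike, %d spontaneous)", j, sj.shape[0], pj.shape[0])
            continue
        sm, pm = sj.mean(axis=0), pj.mean(axis=0)
        diffs[j] = (sm - pm).reshape(H, W)
        spike_means[j] = sm.reshape(H, W)
        spont_means[j] = pm.reshape(H, W)
        entry = {"n_spike": int(sj.shape[0]), "n_spont": int(pj.shape[0])}
        if reference_map is not None:
            entry["r_raw"] = map_similarity(spike_means[j], reference_map)
            entry["r_diff"] = map_similarity(diffs[j], reference_map)
        report[j] = entry
    # conservation: spike-count-weighted mean of partition means = overall mean
    overall = spike_set.vectors.mean(axis=0).reshape(H, W)
    return {"diff_maps": diffs, "spike_means": spike_means,
            "spont_means": spont_means, "report": report, "skipped": skipped,
            "all_spike_mean": overall}
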