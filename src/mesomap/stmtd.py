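"""STM temporal dynamics: ROI trace extraction, normalisation, resampling,
multi-ROI matrices and PCA + k-means classification into the three
event-triggered patterns (spike-triggered excitation, spike-triggered
inhibition, and pre-event inhibition with a brief rebound)."""

from __future__ import annotations

import logging
import re
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core_io import ROISet
from .stamap import StaMovie, _peak_window_slice

logger = logging.getLogger("mesomap")

__all__ = [
    "STMTD",
    "PatternModel",
    "stmtd_extract",
    "stmtd_normalize",
    "resample_stmtd",
    "classify_stmtds",
    "multi_roi_matrix",
    "read_trace_file",
    "write_trace_file",
    "count_trace_archive",
]


@dataclass
class STMTD:
    """The −3…+3 s time course of the extremal pixel inside one ROI."""

    trace: np.ndarray
    pixel: tuple[int, int]
    roi_name: str = ""
    unit_id: str = ""
    frame_rate_hz: float | None = None
    window_s: tuple[float, float] = (-3.0, 3.0)

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=np.float64)

    @property
    def peak_pct(self) -> float:
        """Extremum magnitude in percent ΔF/F0 (selection-filter quantity)."""
        return float(np.abs(self.trace).max() * 100.0)


@dataclass
class PatternModel:
    """Fitted PCA + k-means model over a population of temporal dynamics."""

    k: int
    n_components: int
    cluster_means: np.ndarray  # k x T
    cluster_sds: np.ndarray  # k x T
    cluster_to_pattern: dict[int, int]
    labels_cluster: np.ndarray
    labels_pattern: np.ndarray
    pca_coords: np.ndarray  # n x n_components
    seed: int

    def pattern_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for p in self.labels_pattern:
            out[int(p)] = out.get(int(p), 0) + 1
        return out


def stmtd_extract(movie: StaMovie, roi_mask: np.ndarray, roi_name: str = "",
                  unit_id: str = "",
                  peak_window_s: tuple[float, float] = (-1.0, 1.0)) -> STMTD:
    """Trace of the maximally activated/depressed pixel inside an ROI.

    The pixel with the largest |ΔF/F0| anywhere in the ±1 s peak window is
    selected; its full −3…+3 s trace and coordinates are returned. Ties are
    broken in row-major scan order.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    sl = _peak_window_slice(movie, peak_window_s)
    win = np.abs(movie.values[sl])  # T_peak x H x W
    strength = win.max(axis=0)
    strength = np.where(roi_mask, strength, -np.inf)
    flat = int(np.argmax(strength))  # row-major tie-break
    r, c = np.unravel_index(flat, strength.shape)
    return STMTD(trace=movie.values[:, r, c].copy(), pixel=(int(r), int(c)),
                 roi_name=roi_name, unit_id=unit_id,
                 frame_rate_hz=movie.frame_rate_hz, window_s=movie.window_s)


def stmtd_normalize(trace: np.ndarray) -> np.ndarray:
    """Scale a trace by its extremum magnitude into [−1, 1], sign preserved."""
    trace = np.asarray(trace, dtype=np.float64)
    peak = np.abs(trace).max()
    if peak == 0:
        raise ValueError("all-zero trace cannot be normalised")
    return trace / peak


def resample_stmtd(trace: np.ndarray, frame_rate_hz: float, target_hz: float = 100.0,
                   window_s: tuple[float, float] = (-3.0, 3.0),
                   allow_any_window: bool = False) -> np.ndarray:
    """Linear interpolation of a trace onto a uniform ``target_hz`` grid.

    A 6 s window at 100 Hz yields 600 samples, matching the trace-file
    convention used for population clustering. The input samples are
    assumed uniform at ``frame_rate_hz`` starting at window_s[0].
    """
    trace = np.asarray(trace, dtype=np.float64)
    lo, hi = window_s
    span = hi - lo
    if not allow_any_window and abs(span - 6.0) > 1e-9:
        raise ValueError("expected a 6 s window; pass allow_any_window=True to override")
    t_in = lo + np.arange(trace.size) / frame_rate_hz
    n_out = int(round(span * target_hz))
    t_out = lo + np.arange(n_out) / target_hz
    return np.interp(t_out, t_in, trace)


def _assign_pattern(mean_trace: np.ndarray, t: np.ndarray) -> int:
    """Map one cluster mean to a pattern id by its pre/post structure.

    pattern 3: depressed before the trigger (negative pre-trigger mean);
    pattern 2: negative post-trigger extremum with non-negative pre mean;
    pattern 1: positive post-trigger extremum.
    """
    pre_mean = mean_trace[t < 0].mean()
    post = mean_trace[t >= 0]
    post_ext = post[np.abs(post).argmax()]
    if pre_mean < -0.05 * np.abs(mean_trace).max():
        return 3
    if post_ext < 0:
        return 2
    return 1


def classify_stmtds(traces: np.ndarray, k: int = 3, n_components: int = 3,
                    seed: int = 0, frame_rate_hz: float = 100.0,
                    window_s: tuple[float, float] = (-3.0, 3.0),
                    normalize: bool = True, n_init: int = 20) -> PatternModel:
    """Cluster a population of temporal dynamics with PCA + k-means.

    Traces (n x T, equal length — resample first) are normalised, centered,
    projected onto ``n_components`` principal components, and partitioned
    by k-means (k-means++ init, ``n_init`` restarts, fixed seed). Clusters
    are then mapped to pattern ids from their mean trace: positive
    post-trigger extremum = 1, negative post-trigger extremum = 2, negative
    pre-trigger mean = 3.
    """
    X = np.asarray(traces, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("traces must be n x T")
    n, T = X.shape
    if n < k:
        raise ValueError(f"need at least k={k} traces, got {n}")
    if normalize:
        peaks = np.abs(X).max(axis=1, keepdims=True)
        if np.any(peaks == 0):
            raise ValueError("all-zero trace in population")
        X = X / peaks
    if np.allclose(X, X[0]):
        raise ValueError("degenerate population: all traces identical")
    n_comp = min(n_components, n, T)
    pca = PCA(n_components=n_comp, random_state=seed)
    coords = pca.fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords)
    lo, hi = window_s
    t = lo + np.arange(T) / frame_rate_hz
    means = np.stack([X[labels == j].mean(axis=0) for j in range(k)])
    sds = np.stack([X[labels == j].std(axis=0) for j in range(k)])
    mapping = {j: _assign_pattern(means[j], t) for j in range(k)}
    pattern_labels = np.array([mapping[j] for j in labels])
    return PatternModel(k=k, n_components=n_comp, cluster_means=means,
                        cluster_sds=sds, cluster_to_pattern=mapping,
                        labels_cluster=labels, labels_pattern=pattern_labels,
                        pca_coords=coords, seed=seed)


def multi_roi_matrix(movies: dict[str, StaMovie], rois: ROISet,
                     min_peak_pct: float = 0.5) -> tuple[np.ndarray, list[str], list[str]]:
    """units x (ROIs · T_win) matrix of normalised ROI temporal dynamics.

    One row per unit; within a row, one T_win block per ROI holding that
    ROI's normalised trace. Blocks whose extremum falls below
    ``min_peak_pct`` percent ΔF/F0 are set to NaN (sub-threshold response).
    Returns (matrix, unit ids, roi names).
    """
    unit_ids = list(movies)
    roi_names = rois.names
    if not unit_ids:
        raise ValueError("no movies supplied")
    T_win = next(iter(movies.values())).values.shape[0]
    out = np.full((len(unit_ids), len(roi_names) * T_win), np.nan)
    for i, uid in enumerate(unit_ids):
        movie = movies[uid]
        if movie.values.shape[0] != T_win:
            raise ValueError("movies have inconsistent window lengths")
        for j, name in enumerate(roi_names):
            td = stmtd_extract(movie, rois[name], roi_name=name, unit_id=uid)
            if td.peak_pct >= min_peak_pct:
                out[i, j * T_win:(j + 1) * T_win] = stmtd_normalize(td.trace)
    return out, unit_ids, roi_names


# ---------------------------------------------------------------------------
# Trace files (one trace per plain-text file, one value per line)


def read_trace_file(path: str | Path) -> np.ndarray:
    vals = [float(line) for line in Path(path).read_text().split()]
    if not vals:
        raise ValueError(f"empty trace file {path}")
    return np.asarray(vals, dtype=np.float64)


def write_trace_file(path: str | Path, trace: np.ndarray) -> Path:
    path = Path(path)
    path.write_text("".join(f"{v:.6f}\n" for v in np.asarray(trace).ravel()))
    return path


def count_trace_archive(path: str | Path,
                        cortical_pattern: str = r"cortex|cortical",
                        subcortical_pattern: str = r"subcort|thalam") -> dict[str, int]:
    """Count ``*traces.txt`` files in a directory or zip archive of
    population trace files, split into cortical/subcortical by filename.

    Returns ``{"total": n, "cortical": nc, "subcortical": ns}``; files whose
    name matches neither pattern count only toward the total.
    """
    path = Path(path)
    if path.is_dir():
        names = [p.name for p in path.rglob("*traces.txt")]
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            names = [Path(n).name for n in zf.namelist() if n.endswith("traces.txt")]
    else:
        raise ValueError(f"{path} is neither a directory nor a zip archive")
    cort = re.compile(cortical_pattern, re.IGNORECASE)
    sub = re.compile(subcortical_pattern, re.IGNORECASE)
    # subcortical takes precedence: "subcortical" also contains "cortical"
    n_s = sum(1 for n in names if sub.search(n))
    n_c = sum(1 for n in names if cort.search(n) and not sub.search(n))
    return {"total": len(names), "cortical": n_c, "subcortical": n_s}
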