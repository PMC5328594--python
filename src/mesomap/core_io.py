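"""Domain types and file IO for spike-triggered mesoscale mapping.

The three core objects are :class:`ImagingStack` (a T x H x W wide-field
fluorescence movie with its frame rate), :class:`SpikeTrain` (sorted event
times in seconds for one unit, plus the metadata the unit-inclusion filters
need), and :class:`ROISet` (named boolean masks over the imaging frame).
Stacks travel as multi-page TIFF, spike trains as plain text with one time
per line, ROI sets as a directory of single-page TIFF masks or a JSON of
polygon vertices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

logger = logging.getLogger("mesomap")

VALID_CHANNELS = ("green_fluorescence", "green_reflectance", "blue_reflectance", "behavior")
VALID_LOCATIONS = ("cortical", "subcortical", "unknown")


@dataclass
class ImagingStack:
    """A wide-field imaging movie.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Fluorescence samples, in camera units or ΔF/F0 fraction. Stored as
        floating point regardless of the camera bit depth.
    frame_rate_hz : float
        Acquisition rate, frames per second.
    channel : str
        One of ``green_fluorescence``, ``green_reflectance``,
        ``blue_reflectance`` or ``behavior``.
    pixel_size_um : float, optional
        Physical pixel pitch after binning (µm/pixel).
    brain_mask : ndarray of bool, shape (H, W), optional
        Pixels considered inside the brain window.
    """

    data: np.ndarray
    frame_rate_hz: float
    channel: str = "green_fluorescence"
    pixel_size_um: float | None = None
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64 if np.asarray(self.data).dtype == np.float64 else np.float32)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(f"stack must be T x H x W with T >= 1, got shape {self.data.shape}")
        if not (1 < self.frame_rate_hz <= 1000):
            raise ValueError(f"frame_rate_hz must be in (1, 1000], got {self.frame_rate_hz}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite samples")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.frame_shape:
                raise ValueError(
                    f"brain_mask shape {self.brain_mask.shape} != frame shape {self.frame_shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def times(self) -> np.ndarray:
        """Start time of every frame, in seconds."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def with_data(self, data: np.ndarray, channel: str | None = None) -> "ImagingStack":
        """Copy of this stack carrying new sample values."""
        return ImagingStack(
            data=np.asarray(data),
            frame_rate_hz=self.frame_rate_hz,
            channel=channel or self.channel,
            pixel_size_um=self.pixel_size_um,
            brain_mask=None if self.brain_mask is None else self.brain_mask.copy(),
        )


@dataclass
class SpikeTrain:
    """Sorted event times (s) for one unit, with sorting/selection metadata."""

    times_s: np.ndarray
    unit_id: str = "unit"
    peak_to_peak_uv: float | None = None
    location: str = "unknown"
    depth_um: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64).ravel()
        if self.times_s.size and self.times_s[0] < 0:
            raise ValueError("spike times must be >= 0")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.location not in VALID_LOCATIONS:
            raise ValueError(f"location must be one of {VALID_LOCATIONS}")

    @property
    def n_spikes(self) -> int:
        return self.times_s.size

    def subset(self, index: np.ndarray, suffix: str = "subset") -> "SpikeTrain":
        times = np.sort(self.times_s[np.asarray(index)])
        return SpikeTrain(
            times_s=times,
            unit_id=f"{self.unit_id}/{suffix}",
            peak_to_peak_uv=self.peak_to_peak_uv,
            location=self.location,
            depth_um=self.depth_um,
        )


@dataclass
class ROISet:
    """Named boolean masks over the imaging frame (e.g. HLS1, FLS1, BCS1, RS,
    V1, M1, PTA, ACC)."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.ndim != 2:
                raise ValueError(f"ROI {name!r} mask must be 2-D")
            if not mask.any():
                raise ValueError(f"ROI {name!r} mask is empty")
            if self.frame_shape is None:
                self.frame_shape = mask.shape
            elif mask.shape != tuple(self.frame_shape):
                raise ValueError(f"ROI {name!r} shape {mask.shape} != {self.frame_shape}")
            clean[name] = mask
        self.masks = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __iter__(self):
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def names(self) -> list[str]:
        return list(self.masks)


# ---------------------------------------------------------------------------
# Readers / writers


def read_stack(path: str | Path, frame_rate_hz: float, channel: str = "green_fluorescence",
               pixel_size_um: float | None = None) -> ImagingStack:
    """Read a single- or multi-page TIFF into an :class:`ImagingStack`.

    Values are preserved bit-exactly as floating-point copies; page count
    becomes T. Raises on a missing file, zero pages or inconsistent page
    shapes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"TIFF has zero pages: {path}")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
    data = np.stack(pages).astype(np.float64)
    if data.ndim == 2:  # single page
        data = data[None]
    return ImagingStack(data=data, frame_rate_hz=frame_rate_hz, channel=channel,
                        pixel_size_um=pixel_size_um)


def write_stack(path: str | Path, stack: ImagingStack | np.ndarray) -> Path:
    """Write a stack (or raw T x H x W array) as a float32 multi-page TIFF."""
    path = Path(path)
    data = stack.data if isinstance(stack, ImagingStack) else np.asarray(stack)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32), photometric="minisblack")
    return path


def read_spikes(path: str | Path, unit_id: str | None = None, **metadata) -> SpikeTrain:
    """Read spike times from a text file, one seconds-valued time per line.

    Times are sorted ascending; exact duplicates are collapsed with a logged
    warning. Empty files and negative times are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such spike file: {path}")
    tokens = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not tokens:
        raise ValueError(f"no events in {path}")
    try:
        times = np.array([float(tok) for tok in tokens], dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric token in {path}: {exc}") from exc
    if np.any(times < 0):
        raise ValueError(f"negative spike time in {path}")
    srt = np.sort(times)
    if np.any(np.diff(srt) < 0) or not np.array_equal(srt, times):
        logger.warning("spike times in %s were out of order; sorted", path)
    uniq = np.unique(srt)
    if uniq.size < srt.size:
        logger.warning("%d duplicate spike times collapsed in %s", srt.size - uniq.size, path)
    return SpikeTrain(times_s=uniq, unit_id=unit_id or path.stem, **metadata)


def write_spikes(path: str | Path, train: SpikeTrain | Iterable[float]) -> Path:
    path = Path(path)
    times = train.times_s if isinstance(train, SpikeTrain) else np.asarray(list(train))
    path.write_text("".join(f"{t:.6f}\n" for t in times))
    return path


def times_to_frames(times_s: np.ndarray, frame_rate_hz: float, n_frames: int,
                    mode: str = "floor") -> tuple[np.ndarray, int]:
    """Map event times (s) to imaging frame indices.

    ``floor`` (default) assigns each event to the frame during which it
    occurred, i = floor(t * rate); ``nearest`` rounds to the closest frame
    start. Events mapping outside [0, n_frames) are dropped; the drop count
    is returned alongside the kept indices.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    times_s = np.asarray(times_s, dtype=np.float64)
    if mode == "floor":
        idx = np.floor(times_s * frame_rate_hz).astype(np.int64)
    elif mode == "nearest":
        idx = np.rint(times_s * frame_rate_hz).astype(np.int64)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = (idx >= 0) & (idx < n_frames)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("times_to_frames: dropped %d/%d events outside [0, %d)",
                    n_dropped, idx.size, n_frames)
    return idx[keep], n_dropped


# ---------------------------------------------------------------------------
# ROI sets


def read_roiset(path: str | Path, frame_shape: tuple[int, int] | None = None) -> ROISet:
    """Read an ROI set.

    ``path`` may be a directory of single-page TIFF masks (file stem = ROI
    name, nonzero = inside) or a JSON file mapping names to polygon vertex
    lists ``[[row, col], ...]`` (requires ``frame_shape``).
    """
    path = Path(path)
    masks: dict[str, np.ndarray] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.tif*")):
            masks[f.stem] = tifffile.imread(f) != 0
    elif path.suffix.lower() == ".json":
        if frame_shape is None:
            raise ValueError("frame_shape required to rasterize polygon ROIs")
        from skimage.draw import polygon2mask

        polys: Mapping[str, list] = json.loads(path.read_text())
        for name, verts in polys.items():
            masks[name] = polygon2mask(frame_shape, np.asarray(verts, dtype=float))
    else:
        raise ValueError(f"unsupported ROI source: {path}")
    if not masks:
        raise ValueError(f"no ROIs found at {path}")
    return ROISet(masks=masks)


def write_roiset(directory: str | Path, rois: ROISet) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in rois.masks.items():
        tifffile.imwrite(directory / f"{name}.tif", mask.astype(np.uint8))
    return directory


def setup_logging(level: int = logging.INFO) -> None:
    """Route mesomap log records to stderr with a compact format."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
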