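"""Seed-pixel correlation maps (SPM), cortex-wide SPM libraries, STM↔SPM
similarity and best-match search, and two-seed superposition fitting.

An SPM is the map of zero-lag Pearson r between one pixel's spontaneous
ΔF/F0 time course and every other pixel's, computed on band-passed
(0.3–3 Hz), global-signal-regressed data. A unit's STM is matched against
a library of SPMs; subcortically driven maps are often better explained by
a non-negative superposition of two SPMs than by any single one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .core_io import ImagingStack

logger = logging.getLogger("mesomap")

__all__ = [
    "SPMLibrary",
    "spm",
    "spm_library",
    "map_similarity",
    "best_match",
    "two_seed_fit",
]


@dataclass
class SPMLibrary:
    """Stack of seed-pixel correlation maps indexed by seed coordinate."""

    maps: np.ndarray  # n_seeds x H x W, r values
    seed_coords: list[tuple[int, int]]
    preprocessing: dict | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3 or self.maps.shape[0] != len(self.seed_coords):
            raise ValueError("maps must be n_seeds x H x W aligned with seed_coords")
        if np.nanmax(np.abs(self.maps)) > 1 + 1e-8:
            raise ValueError("correlation values must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.maps.shape[0]


def spm(stack: ImagingStack, seed: tuple[int, int]) -> np.ndarray:
    """Seed-pixel correlation map: Pearson r of the seed pixel's trace
    against every pixel's trace. The seed's own value is 1."""
    r, c = seed
    data = stack.data.reshape(stack.n_frames, -1).astype(np.float64)
    H, W = stack.frame_shape
    s = data[:, r * W + c]
    s = s - s.mean()
    denom_s = np.sqrt(s @ s)
    if denom_s == 0:
        raise ValueError(f"zero-variance seed pixel {seed}")
    X = data - data.mean(axis=0)
    denom = np.sqrt((X * X).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rmap = (s @ X) / (denom_s * denom)
    rmap[denom == 0] = 0.0
    return np.clip(rmap.reshape(H, W), -1.0, 1.0)


def spm_library(stack: ImagingStack, mask: np.ndarray | None = None,
                stride: int = 2, preprocessing: dict | None = None) -> SPMLibrary:
    """One SPM per seed over the brain mask (optionally on a stride grid).

    Seeding every masked pixel is quadratic in pixel count; the default
    stride-2 grid quarters the library with negligible loss for best-match
    search. Zero-variance seeds are skipped with a log message.
    """
    if mask is None:
        mask = stack.brain_mask if stack.brain_mask is not None else np.ones(stack.frame_shape, bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty seed mask")
    H, W = stack.frame_shape
    grid = np.zeros_like(mask)
    grid[::stride, ::stride] = True
    seeds = [tuple(int(v) for v in rc) for rc in np.argwhere(mask & grid)]
    if not seeds:
        raise ValueError("stride grid removed every seed; lower the stride")
    # one pass of per-pixel standardisation shared by all seeds
    data = stack.data.reshape(stack.n_frames, -1).astype(np.float64)
    X = data - data.mean(axis=0)
    denom = np.sqrt((X * X).sum(axis=0))
    maps = []
    kept = []
    for r, c in seeds:
        j = r * W + c
        if denom[j] == 0:
            logger.info("spm_library: skipping zero-variance seed (%d, %d)", r, c)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            rmap = (X[:, j] @ X) / (denom[j] * denom)
        rmap[denom == 0] = 0.0
        maps.append(np.clip(rmap.reshape(H, W), -1, 1))
        kept.append((r, c))
    return SPMLibrary(maps=np.stack(maps), seed_coords=kept, preprocessing=preprocessing)


def map_similarity(map_a: np.ndarray, map_b: np.ndarray,
                   mask: np.ndarray | None = None) -> float:
    """Pearson r between two maps over the masked pixels."""
    map_a = np.asarray(map_a, dtype=np.float64)
    map_b = np.asarray(map_b, dtype=np.float64)
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a shape")
    if mask is None:
        mask = np.ones(map_a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    a = map_a[mask] - map_a[mask].mean()
    b = map_b[mask] - map_b[mask].mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0 or nb == 0:
        raise ValueError("zero variance in a map over the mask")
    return float((a @ b) / (na * nb))


def best_match(stm_map: np.ndarray, library: SPMLibrary,
               mask: np.ndarray | None = None) -> dict:
    """Best-matching SPM for a map: the library seed with the highest
    Pearson r to the map over the mask.

    Ties go to the first seed in scan order. Returns the winning seed, its
    r, and the full r profile across the library.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    profile = np.array([map_similarity(stm_map, m, mask) for m in library.maps])
    idx = int(np.argmax(profile))
    if np.sum(profile == profile[idx]) > 1:
        logger.info("best_match: tie at r=%.6f broken by scan order", profile[idx])
    return {"seed": library.seed_coords[idx], "r": float(profile[idx]),
            "index": idx, "profile": profile}


def two_seed_fit(stm_map: np.ndarray, spm_a: np.ndarray, spm_b: np.ndarray,
                 mask: np.ndarray | None = None) -> dict:
    """Fit a map as a non-negative superposition of two SPMs.

    Solves min ||stm − w_a spm_a − w_b spm_b|| with w >= 0 over the masked
    pixels and reports the Pearson r between the map and the fit, plus the
    better of the two single-SPM r values for comparison.
    """
    if not (stm_map.shape == spm_a.shape == spm_b.shape):
        raise ValueError("maps must share a shape")
    if mask is None:
        mask = np.ones(stm_map.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    A = np.column_stack([spm_a[mask], spm_b[mask]])
    # collinearity makes the weight split arbitrary even when the fit is good
    s = np.linalg.svd(A - A.mean(axis=0), compute_uv=False)
    if s[-1] == 0 or s[0] / max(s[-1], 1e-300) > 1e8:
        logger.warning("two_seed_fit: SPM pair nearly collinear "
                       "(condition %.2e); weights are not identifiable", s[0] / max(s[-1], 1e-300))
    w, _ = nnls(A, stm_map[mask])
    fitted = w[0] * spm_a + w[1] * spm_b
    r_fit = map_similarity(stm_map, fitted, mask) if fitted[mask].std() > 0 else 0.0
    r_single = max(map_similarity(stm_map, spm_a, mask),
                   map_similarity(stm_map, spm_b, mask))
    return {"weights": (float(w[0]), float(w[1])), "fitted": fitted,
            "r_fit": float(r_fit), "r_best_single": float(r_single)}
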