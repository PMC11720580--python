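"""Mean adaptive thresholding, labeling, seed selection and parameter tuning.

The threshold rule: pixel ``p`` is foreground iff
``img[p] > (1 - s) * mean_w(p)`` where ``mean_w(p)`` is the mean over the
``w x w`` window centered at ``p``, clipped at the image borders (mean over
the in-bounds part only).  Computed exactly with an integral image.

Conventions: strict ``>``; sensitivity ``s`` in (0, 1) — larger ``s``
lowers the threshold, so the foreground set grows monotonically with
``s`` for fixed ``w``.  Coordinates are 0-based with x = column, y = row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "SeedSet",
    "TuneReport",
    "integral_image",
    "window_mean",
    "bradley_threshold",
    "label_components",
    "filter_by_area",
    "select_by_seeds",
    "tune_parameters",
]

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    window_size: int = 31
    sensitivity: float = 0.10
    connectivity: int = 8
    min_area: int = 40
    max_area: int = 1500

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if not 0.0 < self.sensitivity < 1.0:
            raise ValueError("sensitivity must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0 <= self.min_area < self.max_area:
            raise ValueError("require 0 <= min_area < max_area")


@dataclass(frozen=True)
class SeedSet:
    """User-provided (x, y) points, one per cell of interest."""

    points: np.ndarray  # (n, 2) of (x, y)
    labels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=int))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.shape[0])

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        x, y = self.points[:, 0], self.points[:, 1]
        bad = (x < 0) | (x >= w) | (y < 0) | (y >= h)
        if bad.any():
            raise ValueError(f"seeds out of bounds for {h}x{w} image: {self.points[bad].tolist()}")


@dataclass(frozen=True)
class TuneReport:
    grid: tuple[tuple[int, float, float], ...]  # (w, s, success rate)
    best_window: int
    best_sensitivity: float
    best_rate: float
    detected: tuple[tuple[int, int], ...]
    missed: tuple[tuple[int, int], ...]


def integral_image(img: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero top row/left column for 4-lookup sums.

    ``S[i+1, j+1]`` is the sum of ``img[:i+1, :j+1]``; the sum over rows
    ``r0..r1-1`` and cols ``c0..c1-1`` is
    ``S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]``.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    S = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=S[1:, 1:])
    return S


def window_mean(img: np.ndarray, window_size: int) -> np.ndarray:
    """Mean over the w x w window centered at each pixel, clipped at borders."""
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 1")
    S = integral_image(img)
    h, w = img.shape
    half = window_size // 2
    rows = np.arange(h)
    cols = np.arange(w)
    r0 = np.clip(rows - half, 0, h)
    r1 = np.clip(rows + half + 1, 0, h)
    c0 = np.clip(cols - half, 0, w)
    c1 = np.clip(cols + half + 1, 0, w)
    sums = (
        S[np.ix_(r1, c1)] - S[np.ix_(r0, c1)] - S[np.ix_(r1, c0)] + S[np.ix_(r0, c0)]
    )
    counts = np.outer(r1 - r0, c1 - c0)
    return sums / counts


def bradley_threshold(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary foreground mask from the local-mean rule (strict inequality)."""
    img = np.asarray(img, dtype=np.float64)
    if params.window_size >= min(img.shape):
        raise ValueError(
            f"window_size {params.window_size} must be smaller than the "
            f"smallest image dimension {min(img.shape)}"
        )
    means = window_mean(img, params.window_size)
    return img > (1.0 - params.sensitivity) * means


def label_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected regions 1..K in raster-scan order of first pixel."""
    mask = np.asarray(mask).astype(bool)
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab, _ = ndimage.label(mask, structure=structure)
    return _relabel_raster_order(lab)


def _relabel_raster_order(lab: np.ndarray) -> np.ndarray:
    flat = lab.ravel()
    values, first = np.unique(flat, return_index=True)
    keep = values != 0
    values, first = values[keep], first[keep]
    order = np.argsort(first)
    mapping = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    mapping[values[order]] = np.arange(1, values.size + 1)
    return mapping[lab]


def filter_by_area(labels: np.ndarray, min_area: int, max_area: int) -> np.ndarray:
    """Drop components outside [min_area, max_area]; relabel compactly in order."""
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.copy()
    areas = np.bincount(labels.ravel())
    keep = (areas >= min_area) & (areas <= max_area)
    keep[0] = False
    mapping = np.zeros(areas.size, dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return mapping[labels]


def select_by_seeds(
    labels: np.ndarray, seeds: SeedSet
) -> tuple[np.ndarray, list[tuple[int, int]], list[tuple[int, int]]]:
    """Keep only components hit by at least one seed.

    A seed is DETECTED iff it lands on a labeled pixel.  Two seeds in one
    component select a single object; the merge is logged.  The workflow is
    seed-driven, so an empty seed set is an error.

    Returns ``(selected_labels, detected_seeds, missed_seeds)``.
    """
    if len(seeds) == 0:
        raise ValueError("empty seed set: the workflow is seed-driven by design")
    labels = np.asarray(labels)
    seeds.check_bounds(labels.shape)
    detected: list[tuple[int, int]] = []
    missed: list[tuple[int, int]] = []
    hit_labels: dict[int, list[tuple[int, int]]] = {}
    for x, y in seeds.points:
        lab = int(labels[y, x])
        if lab > 0:
            detected.append((int(x), int(y)))
            hit_labels.setdefault(lab, []).append((int(x), int(y)))
        else:
            missed.append((int(x), int(y)))
    for lab, pts in hit_labels.items():
        if len(pts) > 1:
            log.warning("MERGE component=%d seeds=%s selected as one object", lab, pts)
    selected = np.where(np.isin(labels, list(hit_labels)), labels, 0)
    return _relabel_raster_order(selected), detected, missed


def tune_parameters(
    img: np.ndarray,
    seeds: SeedSet,
    window_sizes: list[int],
    sensitivities: list[float],
    min_area: int = 40,
    max_area: int = 1500,
    connectivity: int = 8,
) -> TuneReport:
    """Grid-evaluate the threshold->label->filter->seed-match chain.

    Success rate per grid point = detected seeds / total seeds.  Ties at
    the maximum are broken toward larger ``w``, then smaller ``s``
    (favoring smoother, less noise-sensitive segmentation).  Per-point
    failures are logged and scored as rate 0.
    """
    if not window_sizes or not sensitivities:
        raise ValueError("window and sensitivity grids must be non-empty")
    if len(seeds) == 0:
        raise ValueError("empty seed set")
    grid: list[tuple[int, float, float]] = []
    best: tuple[float, int, float] | None = None  # (rate, w, s)
    best_result: tuple[list, list] = ([], [])
    for w in window_sizes:
        for s in sensitivities:
            try:
                params = SegmentationParams(
                    window_size=w, sensitivity=s, connectivity=connectivity,
                    min_area=min_area, max_area=max_area,
                )
                mask = bradley_threshold(img, params)
                lab = label_components(mask, connectivity)
                lab = filter_by_area(lab, min_area, max_area)
                _, det, mis = select_by_seeds(lab, seeds)
                rate = len(det) / len(seeds)
            except (ValueError, RuntimeError) as exc:
                log.warning("tune point (w=%d, s=%.3f) failed: %s", w, s, exc)
                rate, det, mis = 0.0, [], [tuple(p) for p in seeds.points]
            grid.append((int(w), float(s), float(rate)))
            better = (
                best is None
                or rate > best[0]
                or (rate == best[0] and (w > best[1] or (w == best[1] and s < best[2])))
            )
            if better:
                best = (rate, int(w), float(s))
                best_result = (det, mis)
    assert best is not None
    return TuneReport(
        grid=tuple(grid),
        best_window=best[1],
        best_sensitivity=best[2],
        best_rate=best[0],
        detected=tuple(best_result[0]),
        missed=tuple(best_result[1]),
    )
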