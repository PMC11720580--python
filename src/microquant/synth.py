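"""Synthetic micrographs, decay histograms and OCR traces with ground truth.

Every generator takes an explicit seed and is deterministic for a fixed
seed.  Scenes carry the exact truth needed to test the downstream stages:
label masks, per-object true statistics, seed points, the noise-free
background field and (for tubular scenes) the generating skeleton graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .flim import DecayHistogram
from .ocr import OCRTrace

__all__ = [
    "SceneParams",
    "MitoSceneParams",
    "CellRecord",
    "NetworkTruth",
    "SyntheticScene",
    "PlacementError",
    "make_cell_scene",
    "make_mito_scene",
    "make_decay",
    "make_stress_trace",
]

#: Mahalanobis radius at which the elliptical-Gaussian profile is truncated;
#: pixels beyond it are exactly zero, which defines the ground-truth mask.
TRUNCATION_SIGMA = 2.5

_DIAG = math.sqrt(2.0)


class PlacementError(RuntimeError):
    """Cell placement failed within the retry budget for the spacing constraint."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters for a field of bright elliptical cells on an uneven background."""

    height: int = 256
    width: int = 256
    n_cells: int = 20
    radius_range: tuple[float, float] = (5.0, 9.0)
    peak_range: tuple[float, float] = (400.0, 800.0)
    eccentricity_range: tuple[float, float] = (1.0, 2.0)
    background_base: float = 100.0
    gradient_amplitude: float = 30.0
    smoothness_scale: float = 64.0
    noise: str = "poisson"  # none | poisson | gaussian
    noise_param: float = 0.0  # gaussian sd; unused for poisson
    min_spacing: float | None = None  # None -> derived from max cell extent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be positive and ordered")
        if self.eccentricity_range[0] < 1:
            raise ValueError("eccentricity must be >= 1")
        if self.background_base < 0 or self.gradient_amplitude < 0:
            raise ValueError("background levels must be non-negative")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def max_extent(self) -> float:
        """Largest possible mask semi-axis (major axis at truncation)."""
        return self.radius_range[1] * math.sqrt(self.eccentricity_range[1])

    @property
    def spacing(self) -> float:
        if self.min_spacing is not None:
            return self.min_spacing
        return 2.0 * self.max_extent + 2.0


@dataclass(frozen=True)
class MitoSceneParams:
    """Parameters for tubular branched networks (mitochondria-like)."""

    height: int = 256
    width: int = 256
    n_networks: int = 6
    branch_counts: tuple[int, ...] = (1, 3, 4, 5)
    branch_length_range: tuple[float, float] = (10.0, 22.0)
    tube_width: int = 3
    intensity: float = 300.0
    background_base: float = 20.0
    noise: str = "poisson"
    noise_param: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 0:
            raise ValueError("n_networks must be >= 0")
        if self.branch_length_range[0] < 2:
            raise ValueError("branch length must be >= 2 px (degenerate geometry)")
        if any(k < 1 or k == 2 for k in self.branch_counts):
            raise ValueError("branch counts must be 1 or >= 3 (2 collinear arms are one branch)")
        if self.tube_width < 1:
            raise ValueError("tube_width must be >= 1")


@dataclass(frozen=True)
class CellRecord:
    label: int
    cx: float
    cy: float
    area_px: int
    true_mean: float


@dataclass(frozen=True)
class NetworkTruth:
    label: int
    branches: int
    junctions: int
    total_length_px: float


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray
    truth_mask: np.ndarray
    background: np.ndarray
    records: tuple[CellRecord, ...]
    seeds: np.ndarray  # (n, 2) of (x, y) int
    skeleton: np.ndarray | None = None
    network_truth: tuple[NetworkTruth, ...] = ()


def _background_field(
    height: int,
    width: int,
    base: float,
    amplitude: float,
    smoothness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    phi = rng.uniform(0, 2 * np.pi)
    proj = (np.cos(phi) * (xx - width / 2) + np.sin(phi) * (yy - height / 2)) / max(
        height, width
    )
    field = base + amplitude * proj
    if amplitude > 0 and smoothness > 0:
        rough = rng.standard_normal((height, width))
        smooth = ndimage.gaussian_filter(rough, smoothness, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            field = field + smooth * (amplitude / 4.0) / sd
    return np.clip(field, 1e-6, None)


def _apply_noise(
    image: np.ndarray, noise: str, noise_param: float, rng: np.random.Generator
) -> np.ndarray:
    if noise == "none":
        return image
    if noise == "poisson":
        return rng.poisson(np.clip(image, 0, None)).astype(float)
    if noise == "gaussian":
        return np.clip(image + rng.normal(0.0, noise_param, image.shape), 0, None)
    raise ValueError(f"unknown noise model {noise!r}")


def make_cell_scene(params: SceneParams) -> SyntheticScene:
    """Render a field of non-overlapping elliptical-Gaussian cells.

    The image is ``background + sum of truncated anisotropic Gaussian
    profiles``, then the noise model is applied.  Ground truth records one
    entry per cell; ``true_mean`` is the mean of the noise-free foreground
    signal (background excluded) over the cell's mask.

    Raises
    ------
    PlacementError
        If ``n_cells`` cannot be placed at the requested spacing within a
        bounded number of retries.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    background = _background_field(
        h, w, params.background_base, params.gradient_amplitude,
        params.smoothness_scale, rng,
    )

    signal = np.zeros((h, w), dtype=float)
    mask = np.zeros((h, w), dtype=np.uint16)
    records: list[CellRecord] = []
    seeds: list[tuple[int, int]] = []

    # draw geometry first so placement can respect per-cell extents
    radii = rng.uniform(*params.radius_range, size=params.n_cells)
    peaks = rng.uniform(*params.peak_range, size=params.n_cells)
    eccs = rng.uniform(*params.eccentricity_range, size=params.n_cells)
    angles = rng.uniform(0, np.pi, size=params.n_cells)
    extents = radii * np.sqrt(eccs)  # major semi-axis of the truncated mask

    centers: list[tuple[int, int]] = []
    for i in range(params.n_cells):
        margin = int(math.ceil(extents[i])) + 1
        if 2 * margin >= min(h, w):
            raise PlacementError(
                f"cell extent {extents[i]:.1f} px does not fit a {h}x{w} frame"
            )
        placed = False
        for _ in range(500):
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            ok = True
            for j, (py, px) in enumerate(centers):
                d = math.hypot(cy - py, cx - px)
                if d < max(params.spacing, extents[i] + extents[j] + 1.5):
                    ok = False
                    break
            if ok:
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{params.n_cells} with min "
                f"center-to-center spacing {params.spacing:.1f} px in a "
                f"{h}x{w} frame after 500 retries"
            )

    for i, (cy, cx) in enumerate(centers):
        label = i + 1
        r, peak, ecc, theta = radii[i], peaks[i], eccs[i], angles[i]
        sigma_geo = r / TRUNCATION_SIGMA
        sig_major = sigma_geo * math.sqrt(ecc)
        sig_minor = sigma_geo / math.sqrt(ecc)
        ext = int(math.ceil(TRUNCATION_SIGMA * sig_major)) + 1
        y0, y1 = max(cy - ext, 0), min(cy + ext + 1, h)
        x0, x1 = max(cx - ext, 0), min(cx + ext + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        dy, dx = yy - cy, xx - cx
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        q = (u / sig_major) ** 2 + (v / sig_minor) ** 2  # squared Mahalanobis
        inside = q <= TRUNCATION_SIGMA**2
        profile = np.where(inside, peak * np.exp(-0.5 * q), 0.0)
        signal[y0:y1, x0:x1] += profile
        mask[y0:y1, x0:x1][inside] = label
        area = int(inside.sum())
        true_mean = float(profile[inside].mean())
        records.append(CellRecord(label, float(cx), float(cy), area, true_mean))
        seeds.append((cx, cy))

    image = _apply_noise(background + signal, params.noise, params.noise_param, rng)
    return SyntheticScene(
        image=image,
        truth_mask=mask,
        background=background,
        records=tuple(records),
        seeds=np.array(seeds, dtype=int).reshape(-1, 2),
    )


def _raster_path_length(path_pixels: np.ndarray) -> float:
    """Step-metric length of an 8-connected pixel path (1 / sqrt(2) per step)."""
    if len(path_pixels) < 2:
        return 0.0
    steps = np.abs(np.diff(path_pixels, axis=0))
    return float(np.sum(np.where(steps.sum(axis=1) == 2, _DIAG, 1.0)))


def make_mito_scene(params: MitoSceneParams) -> SyntheticScene:
    """Render tubular branched networks with exact skeleton ground truth.

    Each network is either a single straight branch (branches=1,
    junctions=0) or a star of k >= 3 arms around one junction.  The ground
    truth (branch/junction counts, total length in the orthogonal/diagonal
    step metric) comes from the generating polyline graph, independent of
    any later re-skeletonization.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    l_max = params.branch_length_range[1]
    margin = int(math.ceil(l_max)) + params.tube_width + 2
    if 2 * margin >= min(h, w):
        raise PlacementError("networks do not fit the frame at the requested length")

    skeleton = np.zeros((h, w), dtype=bool)
    mask = np.zeros((h, w), dtype=np.uint16)
    truths: list[NetworkTruth] = []
    seeds: list[tuple[int, int]] = []
    centers: list[tuple[int, int]] = []
    min_center_dist = 2 * l_max + 2 * params.tube_width + 2

    selem = disk(max(params.tube_width // 2, 1))
    for i in range(params.n_networks):
        placed = False
        for _ in range(500):
            cy = int(rng.integers(margin, h - margin))
            cx = int(rng.integers(margin, w - margin))
            if all(math.hypot(cy - py, cx - px) >= min_center_dist for py, px in centers):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place network {i + 1}/{params.n_networks} at "
                f"min distance {min_center_dist:.0f} px after 500 retries"
            )
        centers.append((cy, cx))

        k = int(rng.choice(params.branch_counts))
        net_skel = np.zeros((h, w), dtype=bool)
        total_len = 0.0
        if k == 1:
            theta = rng.uniform(0, np.pi)
            length = rng.uniform(*params.branch_length_range)
            y1 = cy + int(round(length * math.sin(theta)))
            x1 = cx + int(round(length * math.cos(theta)))
            rr, cc = draw_line(cy, cx, y1, x1)
            net_skel[rr, cc] = True
            total_len = _raster_path_length(np.column_stack([rr, cc]))
            branches, junctions = 1, 0
        else:
            base = rng.uniform(0, 2 * np.pi)
            jitter = rng.uniform(-0.15, 0.15, size=k)
            for a in range(k):
                theta = base + 2 * np.pi * a / k + jitter[a]
                length = rng.uniform(*params.branch_length_range)
                y1 = cy + int(round(length * math.sin(theta)))
                x1 = cx + int(round(length * math.cos(theta)))
                rr, cc = draw_line(cy, cx, y1, x1)
                net_skel[rr, cc] = True
                total_len += _raster_path_length(np.column_stack([rr, cc]))
            branches, junctions = k, 1

        skeleton |= net_skel
        tube = dilation(net_skel, selem)
        mask[tube] = i + 1
        truths.append(NetworkTruth(i + 1, branches, junctions, total_len))
        seeds.append((cx, cy))

    # drawn lines can meet in solid 2x2 blocks near junctions; prune so the
    # stored skeleton honors the 1-px contract of the network census
    from .morphology import _prune_blocks

    skeleton = _prune_blocks(skeleton)

    background = np.full((h, w), params.background_base, dtype=float)
    signal = params.intensity * ndimage.gaussian_filter((mask > 0).astype(float), 0.8)
    image = _apply_noise(background + signal, params.noise, params.noise_param, rng)
    records = tuple(
        CellRecord(t.label, float(sx), float(sy), int(np.sum(mask == t.label)), float("nan"))
        for t, (sx, sy) in zip(truths, seeds)
    )
    return SyntheticScene(
        image=image,
        truth_mask=mask,
        background=background,
        records=records,
        seeds=np.array(seeds, dtype=int).reshape(-1, 2),
        skeleton=skeleton,
        network_truth=tuple(truths),
    )


def make_decay(
    tau_ns: float,
    amplitude: float,
    baseline: float = 0.0,
    n_bins: int = 256,
    bin_width_ns: float = 0.05,
    mode: str = "expected",
    seed: int = 0,
) -> DecayHistogram:
    """Mono-exponential decay histogram: ``A*exp(-t/tau) + b`` per bin.

    ``mode="expected"`` returns the noise-free expectation; ``"poisson"``
    draws integer counts per bin with that mean.
    """
    if tau_ns <= 0:
        raise ValueError("tau must be positive")
    if bin_width_ns <= 0:
        raise ValueError("bin_width must be positive")
    if mode not in ("expected", "poisson"):
        raise ValueError(f"unknown mode {mode!r}")
    t = (np.arange(n_bins) + 0.5) * bin_width_ns
    expected = amplitude * np.exp(-t / tau_ns) + baseline
    if mode == "expected":
        counts = expected
    else:
        counts = np.random.default_rng(seed).poisson(expected).astype(float)
    return DecayHistogram(time_ns=t, counts=counts, bin_width_ns=bin_width_ns)


def make_stress_trace(
    phase_levels: tuple[float, float, float, float],
    n_per_phase: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_min: float = 6.5,
    label: str = "",
) -> OCRTrace:
    """Four-phase OCR trace (baseline, oligomycin, FCCP, rotenone/antimycin)."""
    levels = tuple(float(v) for v in phase_levels)
    if len(levels) != 4:
        raise ValueError("exactly 4 phase levels required")
    if any(v < 0 for v in levels):
        raise ValueError("negative rates rejected")
    if n_per_phase < 1:
        raise ValueError("n_per_phase must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.repeat(levels, n_per_phase).astype(float)
    if noise_sd > 0:
        values = np.clip(values + rng.normal(0.0, noise_sd, values.size), 0, None)
    times = np.arange(values.size, dtype=float) * dt_min
    b = (n_per_phase, 2 * n_per_phase, 3 * n_per_phase)
    return OCRTrace(time_min=times, ocr=values, boundaries=b, label=label)
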