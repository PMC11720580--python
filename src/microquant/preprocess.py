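"""Noise suppression and background-illumination correction.

Stages: small-kernel Gaussian despeckle, large-kernel background field
estimation (with foreground exclusion by normalized convolution, or from
user-supplied cell-free ROIs), and division by the unit-mean field so the
global intensity scale is preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk

log = logging.getLogger(__name__)

__all__ = [
    "PreprocessParams",
    "despeckle",
    "median_despeckle",
    "estimate_background",
    "correct_background",
    "find_candidate_foreground",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Kernel scales and background-sampling mode.

    ``sigma_large`` should be much larger than the typical cell radius; a
    warning is emitted if it is below 3x ``expected_cell_diameter``.
    """

    sigma_small: float = 1.0
    sigma_large: float = 64.0
    background_mode: str = "mask_excluded"  # or "sampled_rois"
    background_rois: tuple[tuple[int, int, int, int], ...] = ()  # (y0,x0,y1,x1)
    expected_cell_diameter: float = 16.0
    subtract: bool = False  # subtraction instead of division, for comparison

    def __post_init__(self) -> None:
        if not 0 < self.sigma_small < self.sigma_large:
            raise ValueError("require 0 < sigma_small < sigma_large")
        if self.background_mode not in ("mask_excluded", "sampled_rois"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")


def _check_finite(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    return img


def despeckle(img: np.ndarray, sigma_small: float = 1.0) -> np.ndarray:
    """Small-kernel Gaussian smoothing (reflective borders).

    Shape-preserving; a sub-half-pixel sigma degenerates to the identity.
    """
    img = _check_finite(img)
    if sigma_small <= 0:
        raise ValueError("sigma_small must be positive")
    return ndimage.gaussian_filter(img, sigma_small, mode="reflect")


def median_despeckle(img: np.ndarray, size: int = 3) -> np.ndarray:
    """Median-filter alternative (the classic "despeckle"); not the default."""
    img = _check_finite(img)
    if size < 1 or size % 2 == 0:
        raise ValueError("size must be odd and >= 1")
    return ndimage.median_filter(img, size=size, mode="reflect")


def find_candidate_foreground(img: np.ndarray, dilate_radius: int = 3) -> np.ndarray:
    """Coarse bright-object detector for automatic background sampling.

    Flags pixels above ``median + 3 * 1.4826 * MAD`` (robust outlier rule),
    then dilates.  On images without bright outliers (e.g. a pure gradient)
    nothing is flagged, so background estimation sees the whole frame.
    """
    img = _check_finite(img)
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    fg = img > med + 3.0 * 1.4826 * mad if mad > 0 else np.zeros(img.shape, bool)
    if dilate_radius > 0 and fg.any():
        fg = dilation(fg, disk(dilate_radius))
    return fg


def estimate_background(
    img: np.ndarray,
    params: PreprocessParams = PreprocessParams(),
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Estimate the smooth background-illumination field.

    ``mask_excluded`` mode in-fills foreground pixels by normalized
    convolution over background pixels only (the large-kernel blur and the
    in-fill are one operation).  ``sampled_rois`` mode uses only the
    supplied cell-free rectangles as support.

    Raises
    ------
    ValueError
        If the excluded area covers more than 90% of the frame
        (insufficient background support).
    """
    img = _check_finite(img)
    if params.sigma_large < 3.0 * params.expected_cell_diameter:
        warnings.warn(
            f"sigma_large={params.sigma_large} is below 3x the expected cell "
            f"diameter ({params.expected_cell_diameter}); the field may follow cells",
            stacklevel=2,
        )

    if params.background_mode == "sampled_rois":
        if not params.background_rois:
            raise ValueError("sampled_rois mode requires background_rois")
        support = np.zeros(img.shape, dtype=bool)
        for y0, x0, y1, x1 in params.background_rois:
            support[y0:y1, x0:x1] = True
    else:
        if exclusion_mask is not None:
            excl = np.asarray(exclusion_mask) > 0
            if excl.shape != img.shape:
                raise ValueError("exclusion mask shape mismatch")
        else:
            excl = find_candidate_foreground(img)
        support = ~excl

    frac = support.mean()
    if frac < 0.1:
        raise ValueError(
            f"only {frac:.0%} of pixels available as background support; "
            "need at least 10% (exclusion covers > 90%)"
        )

    w = support.astype(float)
    num = ndimage.gaussian_filter(img * w, params.sigma_large, mode="reflect")
    den = ndimage.gaussian_filter(w, params.sigma_large, mode="reflect")
    tiny = np.finfo(float).tiny
    field = num / np.maximum(den, tiny)
    # guard strict positivity for the divisive correction downstream
    floor = max(float(field[den > 1e-12].min()) * 1e-6, tiny) if np.any(den > 1e-12) else tiny
    return np.maximum(field, floor)


def correct_background(
    img: np.ndarray, field: np.ndarray, subtract: bool = False
) -> np.ndarray:
    """Flatten illumination by dividing by the unit-mean field.

    ``out = img / (field / mean(field))`` — preserves the global intensity
    scale exactly; a constant field is the identity.  ``subtract=True``
    switches to ``img - field + mean(field)`` for comparison.
    """
    img = _check_finite(img)
    field = np.asarray(field, dtype=float)
    if field.shape != img.shape:
        raise ValueError(f"field shape {field.shape} != image shape {img.shape}")
    if np.any(field <= 0) or not np.all(np.isfinite(field)):
        raise ValueError("background field must be strictly positive and finite")
    mean = float(field.mean())
    if subtract:
        out = img - field + mean
    else:
        out = img / (field / mean)
    return np.clip(out, 0.0, None)
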