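"""Per-cell quantification, treated/control ratios, assay fractions, statistics.

Group statistics follow the study conventions: mean +/- SEM summaries,
one-way ANOVA with Tukey-Kramer post hoc adjustment (studentized range,
unequal n supported).  The ANOVA/Tukey math is written out from the sums
of squares so it can be cross-checked against independent references.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

log = logging.getLogger(__name__)

__all__ = [
    "CellMeasurement",
    "RatioResult",
    "GroupTable",
    "AnovaResult",
    "measure_cells",
    "pbm_ratio",
    "wound_closure",
    "wound_area",
    "brdu_fraction",
    "count_colocalized",
    "anova_tukey",
    "summarize",
]


@dataclass(frozen=True)
class CellMeasurement:
    label: int
    mean_intensity: float
    area_px: int
    centroid: tuple[float, float]  # (x, y)


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    sem: float
    n_treated: int
    n_control: int
    mean_treated: float
    mean_control: float


@dataclass(frozen=True)
class GroupTable:
    """Labeled replicate groups; needs >= 2 groups of >= 2 values for ANOVA."""

    groups: list[tuple[str, list[float]]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("at least 2 groups required")
        for name, vals in self.groups:
            if len(vals) < 2:
                raise ValueError(f"group {name!r} needs at least 2 values")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    tukey: list[tuple[str, str, float, float]]  # (group a, group b, mean diff, adj p)
    alpha: float
    exact_separation: bool = False

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _, p in self.tukey if p < self.alpha]


def measure_cells(img: np.ndarray, labels: np.ndarray) -> list[CellMeasurement]:
    """One record per label: mean over exactly the labeled pixels of ``img``."""
    img = np.asarray(img, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != img.shape:
        raise ValueError("labels must align with the image")
    n = int(labels.max())
    if n == 0:
        log.warning("empty label set: no objects to measure")
        return []
    idx = np.arange(1, n + 1)
    present = np.isin(idx, labels)
    means = ndimage.mean(img, labels, idx)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    coms = ndimage.center_of_mass(np.ones_like(img), labels, idx)
    out = []
    for i, lab in enumerate(idx):
        if not present[i]:
            continue
        cy, cx = coms[i]
        out.append(
            CellMeasurement(
                label=int(lab),
                mean_intensity=float(means[i]),
                area_px=int(areas[i]),
                centroid=(float(cx), float(cy)),
            )
        )
    return out


def pbm_ratio(treated: list[float], control: list[float]) -> RatioResult:
    """Treated/control ratio of group means with first-order error propagation.

    ``ratio = mean(treated) / mean(control)``;
    ``sem = ratio * sqrt((sem_t/mean_t)^2 + (sem_c/mean_c)^2)``.
    Single-value groups contribute zero SEM.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    mt, mc = float(t.mean()), float(c.mean())
    if mc <= 0:
        raise ValueError(f"control mean must be positive, got {mc}")
    ratio = mt / mc
    sem_t = float(t.std(ddof=1) / math.sqrt(t.size)) if t.size > 1 else 0.0
    sem_c = float(c.std(ddof=1) / math.sqrt(c.size)) if c.size > 1 else 0.0
    rel = 0.0
    if mt != 0:
        rel = (sem_t / mt) ** 2 + (sem_c / mc) ** 2
    return RatioResult(
        ratio=ratio,
        sem=abs(ratio) * math.sqrt(rel),
        n_treated=int(t.size),
        n_control=int(c.size),
        mean_treated=mt,
        mean_control=mc,
    )


def wound_closure(area_t0: float, area_t: float) -> float:
    """Relative closure ``(area_t0 - area_t) / area_t0`` (1 = fully closed)."""
    if area_t0 <= 0:
        raise ValueError("initial wound area must be positive")
    if area_t < 0:
        raise ValueError("wound area cannot be negative")
    return min((area_t0 - area_t) / area_t0, 1.0)


def wound_area(
    img: np.ndarray,
    variance_window: int = 31,
    min_fraction: float = 0.01,
) -> float:
    """Cell-free scratch area (px^2) from a local-variance texture mask.

    Cell-covered regions are textured (high windowed variance), the
    scratch is smooth; the scratch is taken as the largest connected
    low-variance component.  Raises when no candidate exceeds
    ``min_fraction`` of the frame.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    m = ndimage.uniform_filter(img, variance_window, mode="reflect")
    m2 = ndimage.uniform_filter(img**2, variance_window, mode="reflect")
    var = np.clip(m2 - m**2, 0, None)
    sd = np.sqrt(var)
    try:
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(sd)
    except ValueError as exc:  # constant map
        raise ValueError("variance map is degenerate; no scratch found") from exc
    smooth = sd < thr
    # a genuine scratch is near noise-level texture: require clear contrast
    # between the low- and high-variance classes, otherwise the Otsu split
    # is just carving up one continuous texture
    mu_low = float(sd[smooth].mean()) if smooth.any() else 0.0
    mu_high = float(sd[~smooth].mean()) if (~smooth).any() else 0.0
    if mu_high <= 0 or mu_low > 0.5 * mu_high:
        raise ValueError(
            "no scratch found: low/high variance classes are not separated "
            f"(mean sd {mu_low:.2f} vs {mu_high:.2f})"
        )
    lab, k = ndimage.label(smooth)
    if k == 0:
        raise ValueError("no low-variance candidate region found")
    areas = np.bincount(lab.ravel())[1:]
    best_label = int(np.argmax(areas)) + 1
    # the windowed variance marks a half-window transition zone as textured;
    # dilating the component by that margin undoes the erosion
    region = ndimage.binary_dilation(
        lab == best_label, iterations=variance_window // 2
    )
    area = int(np.count_nonzero(region))
    if area < min_fraction * img.size:
        raise ValueError(
            f"largest low-variance region ({area} px) is below "
            f"{min_fraction:.0%} of the frame; no scratch found"
        )
    return float(area)


def count_colocalized(
    nuclei_labels: np.ndarray, marker_labels: np.ndarray
) -> tuple[int, int]:
    """Count nuclei whose centroid lies inside a marker-channel object.

    Returns ``(n_positive, n_total)``.  Centroid containment is robust to
    small channel misregistration.
    """
    nuclei_labels = np.asarray(nuclei_labels)
    marker = np.asarray(marker_labels) > 0
    if marker.shape != nuclei_labels.shape:
        raise ValueError("channel shapes differ")
    records = measure_cells(np.zeros_like(nuclei_labels, dtype=float), nuclei_labels)
    n_total = len(records)
    n_pos = 0
    for rec in records:
        x, y = (int(round(v)) for v in rec.centroid)
        y = min(max(y, 0), marker.shape[0] - 1)
        x = min(max(x, 0), marker.shape[1] - 1)
        if marker[y, x]:
            n_pos += 1
    return n_pos, n_total


def brdu_fraction(n_positive: int, n_total: int) -> float:
    """Positive-nuclei fraction in [0, 1]."""
    if n_total <= 0:
        raise ValueError("total nucleus count must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("require 0 <= n_positive <= n_total")
    return n_positive / n_total


def anova_tukey(groups: GroupTable, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey-Kramer pairwise adjustment.

    F is computed from the between/within sums of squares; pairwise
    adjusted p-values use the studentized-range distribution with the
    Tukey-Kramer standard error for unequal group sizes.  Zero
    within-group variance with unequal means yields ``F = inf`` with the
    ``exact_separation`` flag (equal means yield ``F = 0``).

    A normality pre-check (Shapiro-Wilk per group) logs a warning only;
    the analysis always proceeds parametrically.
    """
    names = [g for g, _ in groups.groups]
    data = [np.asarray(v, dtype=float) for _, v in groups.groups]
    for name, vals in zip(names, data):
        if vals.size >= 3:
            try:
                p_norm = stats.shapiro(vals).pvalue
                if p_norm < 0.05:
                    log.warning("NORMALITY group=%s shapiro_p=%.4g", name, p_norm)
            except ValueError:
                pass

    k = len(data)
    ns = np.array([v.size for v in data])
    n_total = int(ns.sum())
    grand = float(np.concatenate(data).mean())
    means = np.array([v.mean() for v in data])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((v - v.mean()) ** 2) for v in data))
    dfb, dfw = k - 1, n_total - k

    # equal group means leave SSB at rounding-noise level; snap so F is
    # exactly 0 (anything below 1e-12 of the total SS is beyond precision)
    if ssb + ssw > 0 and ssb < 1e-12 * (ssb + ssw):
        ssb = 0.0

    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, _tukey_pairs(names, means, ns, 0.0, dfw, degenerate=True), alpha)
        return AnovaResult(
            math.inf, 0.0, _tukey_pairs(names, means, ns, 0.0, dfw, degenerate=True),
            alpha, exact_separation=True,
        )

    msb = ssb / dfb
    msw = ssw / dfw
    f_stat = msb / msw
    p = float(stats.f.sf(f_stat, dfb, dfw))
    return AnovaResult(f_stat, p, _tukey_pairs(names, means, ns, msw, dfw), alpha)


def _tukey_pairs(names, means, ns, msw, dfw, degenerate=False):
    k = len(names)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            if degenerate or msw == 0.0 or dfw < 1:
                p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, dfw))
            pairs.append((names[i], names[j], diff, p_adj))
    return pairs


def summarize(values: list[float]) -> tuple[float, float]:
    """Mean and SEM (sample SD / sqrt(n)); n < 2 is an error."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM requires at least 2 values")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))
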