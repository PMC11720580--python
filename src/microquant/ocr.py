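"""Mito-stress-test metrics from oxygen-consumption-rate (OCR) traces.

A trace has four phases separated by three injections (oligomycin, FCCP,
rotenone/antimycin A).  Metric conventions:

* non-mitochondrial = mean of phase-4 values
* basal             = last phase-1 value - non-mitochondrial
* ATP-linked        = last phase-1 value - min of phase-2 values
  (oligomycin-sensitive OCR; labeled as such, not a pmol-ATP rate)
* maximal           = max of phase-3 values - non-mitochondrial
* spare             = maximal - basal
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OCRTrace", "StressMetrics", "stress_metrics", "group_compare"]


@dataclass(frozen=True)
class OCRTrace:
    """Time-ordered OCR values with the three injection boundaries.

    ``boundaries[k]`` is the index of the first measurement of phase
    ``k+2`` (phases are 1-based).  Boundaries must be strictly increasing
    and interior so every phase has at least one measurement.
    """

    time_min: np.ndarray
    ocr: np.ndarray
    boundaries: tuple[int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.ocr, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "ocr", v)
        object.__setattr__(self, "boundaries", tuple(int(b) for b in self.boundaries))
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("time_min and ocr must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("OCR values must be finite")
        if np.any(v < 0):
            raise ValueError("negative OCR rates rejected")
        b = self.boundaries
        if len(b) != 3:
            raise ValueError("exactly 3 injection boundaries required")
        if not (0 < b[0] < b[1] < b[2] < t.size):
            raise ValueError(
                f"boundaries {b} must be strictly increasing and interior to "
                f"a trace of length {t.size}"
            )

    def phase(self, k: int) -> np.ndarray:
        """OCR values of phase ``k`` (1..4)."""
        edges = (0, *self.boundaries, self.ocr.size)
        if not 1 <= k <= 4:
            raise ValueError("phase index must be 1..4")
        return self.ocr[edges[k - 1] : edges[k]]


@dataclass(frozen=True)
class StressMetrics:
    non_mito: float
    basal: float
    atp_linked: float
    maximal: float
    spare: float
    negative_basal_flag: bool = False


def stress_metrics(trace: OCRTrace) -> StressMetrics:
    """Decompose an OCR trace into the standard mito-stress components.

    A negative basal value is flagged (not clipped); adding a constant to
    the whole trace shifts only ``non_mito`` (exact linearity).
    """
    p1, p2, p3, p4 = (trace.phase(k) for k in (1, 2, 3, 4))
    non_mito = float(np.mean(p4))
    last_basal = float(p1[-1])
    basal = last_basal - non_mito
    atp_linked = last_basal - float(np.min(p2))
    maximal = float(np.max(p3)) - non_mito
    return StressMetrics(
        non_mito=non_mito,
        basal=basal,
        atp_linked=atp_linked,
        maximal=maximal,
        spare=maximal - basal,
        negative_basal_flag=basal < 0,
    )


def group_compare(
    metrics_per_condition: dict[str, list[StressMetrics]],
    metric: str = "maximal",
    alpha: float = 0.05,
    strict_n: int | None = None,
):
    """ANOVA + Tukey on one stress metric across conditions.

    Wells are the independent unit: each :class:`StressMetrics` entry is
    one well.  With ``strict_n`` set, conditions with fewer wells raise.
    """
    from .quantify_stats import GroupTable, anova_tukey

    if strict_n is not None:
        short = {g: len(ms) for g, ms in metrics_per_condition.items() if len(ms) < strict_n}
        if short:
            raise ValueError(
                f"strict mode requires n >= {strict_n} wells per condition; got {short}"
            )
    table = GroupTable(
        [
            (group, [float(getattr(m, metric)) for m in ms])
            for group, ms in metrics_per_condition.items()
        ]
    )
    return anova_tukey(table, alpha=alpha)
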