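"""Mitochondrial morphology and skeleton-network connectivity metrics.

Object shape: area (pixel count), Crofton 4-direction perimeter,
form factor ``P^2 / (4 pi A)`` (1 for a circle, grows with complexity) and
the major/minor axis ratio of the second-moment ellipse.

Network connectivity: skeleton pixels are classified by their 8-neighbor
count (1 = endpoint, 2 = internal, >= 3 = junction); branches are maximal
paths between terminals with length 1 per orthogonal and sqrt(2) per
diagonal step; 8-connected clusters of junction pixels count as ONE
junction (thinning can split one biological node into adjacent pixels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops
from skimage.morphology import skeletonize as _skimage_skeletonize

__all__ = [
    "MorphologyRecord",
    "NetworkRecord",
    "object_metrics",
    "skeletonize",
    "network_metrics",
    "condition_summary",
]

_SQRT2 = math.sqrt(2.0)
_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class MorphologyRecord:
    label: int
    area_px: int
    perimeter_px: float
    form_factor: float  # NaN for degenerate (< 4 px) objects
    aspect_ratio: float  # NaN for degenerate objects
    circularity: float  # 1 / form_factor, derived convenience column
    degenerate: bool = False


@dataclass(frozen=True)
class NetworkRecord:
    total_length_px: float
    branches: int
    junctions: int
    per_network: tuple[tuple[int, int, int, float], ...]  # (id, branches, junctions, length)


def object_metrics(labels: np.ndarray, crofton: bool = True) -> list[MorphologyRecord]:
    """Shape metrics per labeled object.

    Objects below 4 px have degenerate second moments; they are flagged
    and their form factor / aspect ratio reported as NaN.  ``crofton=False``
    switches to the naive boundary-step perimeter for comparison.
    """
    labels = np.asarray(labels)
    records: list[MorphologyRecord] = []
    for prop in regionprops(labels):
        area = int(prop.area)
        perim = float(prop.perimeter_crofton if crofton else prop.perimeter)
        degenerate = area < 4 or prop.axis_minor_length == 0
        if degenerate:
            ff = ar = circ = float("nan")
        else:
            ff = perim**2 / (4.0 * math.pi * area)
            ar = float(prop.axis_major_length / prop.axis_minor_length)
            circ = 1.0 / ff if ff > 0 else float("nan")
        records.append(
            MorphologyRecord(
                label=int(prop.label),
                area_px=area,
                perimeter_px=perim,
                form_factor=ff,
                aspect_ratio=ar,
                circularity=circ,
                degenerate=degenerate,
            )
        )
    return records


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px skeleton.

    Thinning can leave solid 2x2 blocks at staircase corners; those are
    pruned by removing simple points (pixels whose foreground neighbors
    stay 8-connected without them) until no block remains.
    """
    mask = np.asarray(mask).astype(bool)
    return _prune_blocks(_skimage_skeletonize(mask))


def _prune_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove simple points from solid 2x2 blocks until none remain."""
    skel = skel.copy()
    eight = np.ones((3, 3), dtype=int)
    while True:
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        ys, xs = np.nonzero(blocks)
        if ys.size == 0:
            return skel
        removed_any = False
        for y, x in zip(ys, xs):
            for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
                py, px = y + dy, x + dx
                if not skel[py, px]:
                    continue
                y0, x0 = max(py - 1, 0), max(px - 1, 0)
                win = skel[y0 : py + 2, x0 : px + 2].copy()
                win[py - y0, px - x0] = False
                n_nb = int(win.sum())
                _, n_comp = ndimage.label(win, structure=eight)
                if n_nb >= 2 and n_comp == 1:
                    skel[py, px] = False
                    removed_any = True
                    break
            if removed_any:
                break
        if not removed_any:
            # no simple point in any block; give up rather than loop forever
            return skel


def _neighbor_degree(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant", cval=0)


def _census(skel: np.ndarray) -> tuple[int, int, float]:
    """(branches, junctions, total length) of one skeleton array."""
    deg = _neighbor_degree(skel)
    junction_px = skel & (deg >= 3)
    endpoint_px = skel & (deg == 1)
    _, n_junctions = ndimage.label(junction_px, structure=np.ones((3, 3)))
    h, w = skel.shape

    def neighbors(p):
        y, x = p
        out = []
        for dy, dx in _OFFSETS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and skel[ny, nx]:
                out.append((ny, nx))
        return out

    def cost(a, b):
        return _SQRT2 if a[0] != b[0] and a[1] != b[1] else 1.0

    terminals = set(map(tuple, np.argwhere(junction_px | endpoint_px)))
    visited_edges: set[frozenset] = set()
    visited_px: set[tuple[int, int]] = set()
    branches = 0
    total_len = 0.0

    for t in sorted(terminals):
        for n in neighbors(t):
            if junction_px[t] and junction_px[n]:
                continue  # edge inside a junction cluster, not a branch
            edge = frozenset((t, n))
            if edge in visited_edges:
                continue
            visited_edges.add(edge)
            visited_px.update((t, n))
            length = cost(t, n)
            prev, cur = t, n
            while cur not in terminals:
                nxt = [p for p in neighbors(cur) if p != prev]
                if not nxt:
                    break  # defensive: dangling pixel misclassified
                length += cost(cur, nxt[0])
                prev, cur = cur, nxt[0]
                visited_px.add(cur)
            visited_edges.add(frozenset((cur, prev)))
            branches += 1
            total_len += length

    # pure cycles: degree-2 loops never reached from any terminal
    remaining = set(map(tuple, np.argwhere(skel & (deg == 2)))) - visited_px
    while remaining:
        start = min(remaining)
        nbrs = neighbors(start)
        prev, cur = start, nbrs[0]
        length = cost(start, cur)
        remaining.discard(start)
        while cur != start:
            remaining.discard(cur)
            nxt = [p for p in neighbors(cur) if p != prev]
            if not nxt:
                break
            length += cost(cur, nxt[0])
            prev, cur = cur, nxt[0]
        branches += 1
        total_len += length

    return branches, int(n_junctions), total_len


def network_metrics(skeleton: np.ndarray) -> NetworkRecord:
    """Branch/junction census of a 1-px skeleton.

    Raises on non-skeletal input (any solid 2x2 block).  Isolated cycles
    with no terminals count as one branch; isolated single pixels
    contribute nothing.  The per-network breakdown is one entry per
    8-connected skeleton component.
    """
    skel = np.asarray(skeleton).astype(bool)
    if skel.ndim != 2:
        raise ValueError("expected a 2-D skeleton mask")
    if np.any(skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]):
        raise ValueError("non-skeletal input: found a solid 2x2 block")

    comp_labels, n_comp = ndimage.label(skel, structure=np.ones((3, 3)))
    per_network = []
    branches = junctions = 0
    total_len = 0.0
    for comp_id in range(1, n_comp + 1):
        b, j, length = _census(comp_labels == comp_id)
        per_network.append((comp_id, b, j, length))
        branches += b
        junctions += j
        total_len += length

    return NetworkRecord(
        total_length_px=total_len,
        branches=branches,
        junctions=junctions,
        per_network=tuple(per_network),
    )


def condition_summary(records_per_image: list[list[MorphologyRecord]]) -> dict:
    """Per-condition totals and means over an image set.

    Totals are sums over all objects of all images; means are per-object
    averages (degenerate objects excluded from form factor / aspect ratio).
    """
    all_recs = [r for recs in records_per_image for r in recs]
    if not all_recs:
        return {
            "n_images": len(records_per_image), "n_objects": 0,
            "total_area_px": 0.0, "total_perimeter_px": 0.0,
            "mean_area_px": float("nan"), "mean_perimeter_px": float("nan"),
            "mean_form_factor": float("nan"), "mean_aspect_ratio": float("nan"),
        }
    areas = np.array([r.area_px for r in all_recs], dtype=float)
    perims = np.array([r.perimeter_px for r in all_recs], dtype=float)
    ffs = np.array([r.form_factor for r in all_recs], dtype=float)
    ars = np.array([r.aspect_ratio for r in all_recs], dtype=float)
    with np.errstate(invalid="ignore"):
        mean_ff = float(np.nanmean(ffs)) if np.any(~np.isnan(ffs)) else float("nan")
        mean_ar = float(np.nanmean(ars)) if np.any(~np.isnan(ars)) else float("nan")
    return {
        "n_images": len(records_per_image),
        "n_objects": len(all_recs),
        "total_area_px": float(areas.sum()),
        "total_perimeter_px": float(perims.sum()),
        "mean_area_px": float(areas.mean()),
        "mean_perimeter_px": float(perims.mean()),
        "mean_form_factor": mean_ff,
        "mean_aspect_ratio": mean_ar,
    }
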