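"""TIFF and CSV input/output.

Integer TIFF data is promoted to float without rescaling (raw counts are
preserved).  Every CSV written by the toolkit starts with a comment line
carrying the tool version and the hash of the configuration in force.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def read_image(
    path: str | Path, page: int | None = None, channel: int | None = None
) -> np.ndarray:
    """Read a grayscale TIFF as a float image.

    Multi-page files require an explicit ``page``; RGB/multi-channel data
    requires an explicit ``channel``.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            n_pages = len(tif.pages)
            if n_pages > 1:
                if page is None:
                    raise ValueError(
                        f"{path} has {n_pages} pages; pass an explicit page index"
                    )
                data = tif.pages[page].asarray()
            else:
                data = tif.pages[0].asarray()
    except (OSError, tifffile.TiffFileError) as exc:
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc

    if data.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path} has {data.shape[-1] if data.shape[-1] < 5 else data.shape[0]}"
                " channels; pass an explicit channel index"
            )
        data = data[..., channel] if data.shape[-1] <= 4 else data[channel]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {data.shape}")
    return data.astype(np.float64)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a float image or integer label mask as TIFF.

    Label masks (integer dtype) go out as 16-bit; float data as 32-bit.
    """
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer) or img.dtype == bool:
        if img.max() > np.iinfo(np.uint16).max:
            raise ValueError("label values exceed the 16-bit range")
        tifffile.imwrite(Path(path), img.astype(np.uint16))
    else:
        tifffile.imwrite(Path(path), img.astype(np.float32))


def read_seeds(path: str | Path) -> tuple[np.ndarray, list[int] | None]:
    """Read a seed CSV with columns ``x,y[,label]`` (comment lines allowed)."""
    df = pd.read_csv(path, comment="#")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"seed CSV {path} lacks columns {sorted(missing)}")
    pts = df[["x", "y"]].to_numpy(dtype=int)
    labels = df["label"].astype(int).tolist() if "label" in df.columns else None
    return pts, labels


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_csv(path: str | Path, df: pd.DataFrame, config: dict | None = None) -> None:
    """Write an RFC-4180 CSV prefixed by a tool-version/config-hash comment."""
    from . import __version__

    chash = config_hash(config or {})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# microquant v{__version__} config={chash}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_scene(scene, out_dir: str | Path, config: dict | None = None) -> None:
    """Persist a synthetic scene: image/mask TIFFs, truth and seed CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / "image.tif", scene.image)
    write_image(out / "truth_mask.tif", scene.truth_mask.astype(np.uint16))
    write_csv(
        out / "truth.csv",
        pd.DataFrame(
            [
                {
                    "label": r.label, "cx": r.cx, "cy": r.cy,
                    "area_px": r.area_px, "true_mean": r.true_mean,
                }
                for r in scene.records
            ]
        ),
        config,
    )
    write_csv(
        out / "seeds.csv",
        pd.DataFrame(
            {
                "x": scene.seeds[:, 0],
                "y": scene.seeds[:, 1],
                "label": [r.label for r in scene.records],
            }
        ),
        config,
    )


def read_decay_csv(path: str | Path):
    """Read decays from ``time_ns,counts`` or long ``roi_id,time_ns,counts``.

    Returns a dict mapping ROI id (or ``"0"``) to a DecayHistogram.
    """
    from .flim import DecayHistogram

    df = pd.read_csv(path, comment="#")
    need = {"time_ns", "counts"}
    if not need <= set(df.columns):
        raise ValueError(f"decay CSV {path} needs columns {sorted(need)}")

    def build(sub: pd.DataFrame) -> DecayHistogram:
        t = sub["time_ns"].to_numpy(dtype=float)
        widths = np.diff(t)
        if widths.size == 0:
            raise ValueError("decay needs at least 2 bins")
        return DecayHistogram(t, sub["counts"].to_numpy(dtype=float), float(widths[0]))

    if "roi_id" in df.columns:
        return {str(k): build(g.sort_values("time_ns")) for k, g in df.groupby("roi_id")}
    return {"0": build(df.sort_values("time_ns"))}


def read_trace_csv(path: str | Path):
    """Read OCR traces from ``well,group,time_min,ocr_pmol_min,phase``.

    Returns ``{well: (group, OCRTrace)}``.
    """
    from .ocr import OCRTrace

    df = pd.read_csv(path, comment="#")
    need = {"well", "group", "time_min", "ocr_pmol_min", "phase"}
    if not need <= set(df.columns):
        raise ValueError(f"trace CSV {path} needs columns {sorted(need)}")
    out = {}
    for well, sub in df.groupby("well"):
        sub = sub.sort_values("time_min")
        phases = sub["phase"].to_numpy(dtype=int)
        if np.any(np.diff(phases) < 0) or set(np.unique(phases)) != {1, 2, 3, 4}:
            raise ValueError(f"well {well}: phases must be 1..4 in order")
        bounds = tuple(int(np.searchsorted(phases, k)) for k in (2, 3, 4))
        trace = OCRTrace(
            time_min=sub["time_min"].to_numpy(dtype=float),
            ocr=sub["ocr_pmol_min"].to_numpy(dtype=float),
            boundaries=bounds,
            label=str(well),
        )
        out[str(well)] = (str(sub["group"].iloc[0]), trace)
    return out
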