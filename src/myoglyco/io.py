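"""Reading and writing the pipeline's file formats.

Stacks travel as multi-page TIFF (pages = z planes, channels stored as the
first axis of each page or as separate series) plus a JSON sidecar holding
voxel sizes, channel labels and provenance flags.  ROIs are CSV rows
(image_id, role, x0, y0, width, height, excl_y_lo, excl_y_hi); cohort and
replicate tables are plain CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .densitometry import RectROI
from .restoration import ZStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_image",
    "read_image",
    "read_rois",
    "write_rois",
]

_ROI_COLUMNS = ["image_id", "role", "x0", "y0", "width", "height", "excl_y_lo", "excl_y_hi"]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_stack(stack: ZStack, path: str | Path) -> None:
    """Write a stack as (z, channel, y, x) multi-page TIFF with a JSON sidecar."""
    path = Path(path)
    # channel axis second so pages iterate over z, channels interleaved per page
    data = np.moveaxis(stack.intensities, 0, 1).astype(np.float32)
    tifffile.imwrite(path, data, metadata={"axes": "ZCYX"})
    meta = {
        "voxel_size_nm": list(stack.voxel_size),
        "channel_labels": stack.channel_labels,
        "background_subtracted": stack.background_subtracted,
        "unmixed": stack.unmixed,
        "deconvolved": stack.deconvolved,
        "background_levels": stack.background_levels,
        "layout": "ZCYX",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_stack(path: str | Path) -> ZStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if data.ndim == 3:  # single channel
        data = data[:, None]
    intensities = np.moveaxis(data, 1, 0).astype(float)
    return ZStack(
        intensities,
        voxel_size=tuple(meta["voxel_size_nm"]),
        channel_labels=meta.get("channel_labels"),
        background_subtracted=meta.get("background_subtracted", False),
        unmixed=meta.get("unmixed", False),
        deconvolved=meta.get("deconvolved", False),
        background_levels=meta.get("background_levels", []),
    )


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def write_rois(rois: list[RectROI], path: str | Path) -> None:
    rows = []
    for r in rois:
        lo, hi = r.excluded_y_range if r.excluded_y_range else (np.nan, np.nan)
        rows.append((r.image_id, r.role, r.x0, r.y0, r.width, r.height, lo, hi))
    pd.DataFrame(rows, columns=_ROI_COLUMNS).to_csv(path, index=False)


def read_rois(path: str | Path) -> list[RectROI]:
    df = pd.read_csv(path)
    missing = set(_ROI_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"ROI file missing columns: {sorted(missing)}")
    rois = []
    for _, row in df.iterrows():
        excl = None
        if "excl_y_lo" in df.columns and pd.notna(row.get("excl_y_lo")):
            excl = (int(row["excl_y_lo"]), int(row["excl_y_hi"]))
        rois.append(
            RectROI(
                x0=int(row["x0"]), y0=int(row["y0"]),
                width=int(row["width"]), height=int(row["height"]),
                role=str(row["role"]), image_id=str(row["image_id"]),
                excluded_y_range=excl,
            )
        )
    return rois
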