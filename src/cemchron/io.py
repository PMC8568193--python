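"""Reading and writing image stacks, midline sidecars and count reports.

Stacks are greyscale TIFFs, either one multi-page file or a directory of
single-page files ordered lexicographically by filename. Midline control
points travel in a plain CSV sidecar with columns ``slice_index,x,y``
(0-based pixel coordinates, x = column, y = row).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import DEFAULT_VOXEL_SIZE_UM

log = logging.getLogger("cemchron")

_BIT_DEPTH = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclasses.dataclass
class SliceStack:
    """An ordered stack of identically sized 2D greyscale slices."""

    slices: list[np.ndarray]
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("stack must contain at least one slice")
        shape = self.slices[0].shape
        for i, s in enumerate(self.slices):
            if s.ndim != 2:
                raise ValueError(f"slice {i} is not 2D greyscale (shape {s.shape})")
            if s.shape != shape:
                raise ValueError(
                    f"slice {i} has shape {s.shape}, expected {shape}")
            if np.min(s) < 0:
                raise ValueError(f"slice {i} contains negative luminance")
            if np.max(s) > 2 ** self.bit_depth - 1:
                raise ValueError(
                    f"slice {i} exceeds declared {self.bit_depth}-bit range")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape


def _check_page(page: np.ndarray, name: str) -> np.ndarray:
    if page.ndim == 3 and page.shape[-1] in (3, 4):
        raise ValueError(f"{name}: RGB(A) page, expected greyscale")
    if page.ndim != 2:
        raise ValueError(f"{name}: expected a single 2D greyscale page")
    if page.dtype not in _BIT_DEPTH:
        raise ValueError(
            f"{name}: unsupported dtype {page.dtype}, expected uint8/uint16")
    return page


def read_stack(path: str | Path,
               voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> SliceStack:
    """Read a multi-page TIFF or a directory of single-page TIFFs.

    Directory entries are ordered lexicographically by filename. Bit depth
    is inferred from the pixel dtype; mixed depths or dimensions raise a
    format error naming the offending page.
    """
    path = Path(path)
    pages: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise ValueError(f"{path}: no TIFF files found")
        for f in files:
            pages.append(_check_page(tifffile.imread(f), f.name))
    else:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                pages.append(_check_page(page.asarray(), f"{path.name} page {i}"))
    dtypes = {p.dtype for p in pages}
    if len(dtypes) > 1:
        raise ValueError(f"{path}: mixed bit depths {sorted(map(str, dtypes))}")
    bit_depth = _BIT_DEPTH[pages[0].dtype]
    return SliceStack(pages, voxel_size_um=voxel_size_um, bit_depth=bit_depth)


def write_stack(stack: SliceStack, path: str | Path) -> None:
    """Write a stack as one multi-page TIFF, preserving pixel values."""
    tifffile.imwrite(path, np.stack(stack.slices), photometric="minisblack")


def read_midline_sidecar(path: str | Path) -> dict[int, np.ndarray]:
    """Read a midline CSV sidecar into {slice_index: (n, 2) xy array}."""
    df = pd.read_csv(path)
    missing = {"slice_index", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"midline sidecar missing columns {sorted(missing)}")
    out: dict[int, np.ndarray] = {}
    for idx, grp in df.groupby("slice_index", sort=True):
        out[int(idx)] = grp[["x", "y"]].to_numpy(float)
    return out


def write_midline_sidecar(midlines: dict[int, np.ndarray],
                          path: str | Path) -> None:
    rows = [(idx, x, y) for idx in sorted(midlines)
            for x, y in np.asarray(midlines[idx], float)]
    pd.DataFrame(rows, columns=["slice_index", "x", "y"]).to_csv(path, index=False)


def write_report(estimates: Sequence, path: str | Path) -> None:
    """Write slice rows and one summary row per specimen as CSV.

    ``estimates`` holds :class:`~cemchron.counting.IncrementEstimate`
    objects: slice-level entries carry per-transect counts; specimen-level
    entries (``specimen_mean`` set) become summary rows. Output is
    bitwise-stable for a fixed input.
    """
    if not estimates:
        raise ValueError("no estimates to report")
    rows = []
    for est in estimates:
        if est.specimen_mean is not None:
            rows.append({
                "kind": "specimen", "index": est.label,
                "mean_pairs": round(float(est.specimen_mean), 6),
                "sd": round(float(est.slice_sd), 6) if est.slice_sd is not None else "",
                "n": est.n, "rounded_count": est.specimen_count,
            })
        else:
            rows.append({
                "kind": "slice", "index": est.label,
                "mean_pairs": round(float(est.slice_mean), 6),
                "sd": round(float(est.slice_sd), 6),
                "n": est.n, "rounded_count": "",
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    log.info("wrote report with %d rows to %s", len(rows), path)
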