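"""File I/O for masks, histogram stacks and IRF kernels.

Label masks are 16-bit single-page TIFFs.  Per-pixel histogram stacks are
either multi-page TIFFs (one page per time bin) or raw little-endian binary
arrays with a JSON sidecar header carrying the dimensions and time binning.
IRFs load from single-column text or one-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .model import InstrumentResponse, TimeGrid

__all__ = [
    "write_mask",
    "read_mask",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_stack_raw",
    "read_stack_raw",
    "write_irf_text",
    "read_irf",
]


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels must fit in uint16")
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    mask = tifffile.imread(str(path))
    if mask.ndim != 2:
        raise ValueError(f"mask must be a single 2-D page, got shape {mask.shape}")
    return mask.astype(np.uint16)


def _grid_metadata(grid: TimeGrid) -> dict:
    return {
        "n_bins": grid.n_bins,
        "bin_width_ns": grid.bin_width,
        "rep_period_ns": grid.rep_period,
    }


def write_stack_tiff(path: str | Path, stack: np.ndarray, grid: TimeGrid) -> None:
    """Multi-page TIFF, one page per time bin, time-grid metadata embedded."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != grid.n_bins:
        raise ValueError(f"stack must be (n_bins, H, W) with n_bins={grid.n_bins}")
    tifffile.imwrite(
        str(path),
        stack.astype(np.uint32),
        metadata={"flim": _grid_metadata(grid)},
    )


def read_stack_tiff(path: str | Path) -> tuple[np.ndarray, TimeGrid]:
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        meta = (tif.shaped_metadata or [{}])[0].get("flim")
    if stack.ndim != 3:
        raise ValueError(f"stack TIFF must be 3-D, got shape {stack.shape}")
    if meta is None:
        raise ValueError("stack TIFF is missing its time-grid metadata")
    grid = TimeGrid(
        n_bins=int(meta["n_bins"]),
        bin_width=float(meta["bin_width_ns"]),
        rep_period=float(meta["rep_period_ns"]),
    )
    if stack.shape[0] != grid.n_bins:
        raise ValueError("stack page count does not match n_bins in metadata")
    return stack.astype(np.int64), grid


def write_stack_raw(path: str | Path, stack: np.ndarray, grid: TimeGrid) -> None:
    """Raw little-endian uint32 array plus a JSON sidecar header (.json)."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != grid.n_bins:
        raise ValueError(f"stack must be (n_bins, H, W) with n_bins={grid.n_bins}")
    stack.astype("<u4").tofile(path)
    header = {
        "dtype": "<u4",
        "shape": list(stack.shape),
        "order": "C",
        **_grid_metadata(grid),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))


def read_stack_raw(path: str | Path) -> tuple[np.ndarray, TimeGrid]:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    shape = tuple(header["shape"])
    stack = np.fromfile(path, dtype=header["dtype"]).reshape(shape)
    grid = TimeGrid(
        n_bins=int(header["n_bins"]),
        bin_width=float(header["bin_width_ns"]),
        rep_period=float(header["rep_period_ns"]),
    )
    return stack.astype(np.int64), grid


def write_irf_text(path: str | Path, irf: InstrumentResponse) -> None:
    np.savetxt(str(path), irf.kernel, fmt="%.12e")


def read_irf(path: str | Path, grid: TimeGrid) -> InstrumentResponse:
    """Load an IRF kernel from single-column text or a one-page TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        kernel = tifffile.imread(str(path)).astype(float).ravel()
    else:
        kernel = np.loadtxt(str(path), dtype=float).ravel()
    kernel = kernel / kernel.sum()
    return InstrumentResponse(kernel=kernel, grid=grid)
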