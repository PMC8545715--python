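"""TIFF stack input/output for grayscale and binary volumes.

Two layouts are supported: a single multi-page TIFF (``layout="multipage"``)
and a directory with one single-page TIFF per slice (``layout="slices"``),
where slice order is ascending filename order.  Binary masks are stored as
8-bit TIFF with 0 = solid and 255 = pore.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, InvalidParameterError
from .volumes import BinaryVolume, GrayscaleVolume, DEFAULT_VOXEL_EDGE_UM

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]

_SUPPORTED_DTYPES = ("uint8", "uint16", "int16", "float32", "float64")
_LAYOUTS = ("multipage", "slices")

PORE_PIXEL = 255
SOLID_PIXEL = 0


def _check_layout(layout: str) -> None:
    if layout not in _LAYOUTS:
        raise InvalidParameterError(f"layout must be one of {_LAYOUTS}, got {layout!r}")


def _read_array(path: str | Path, layout: str) -> np.ndarray:
    _check_layout(layout)
    path = Path(path)
    if layout == "multipage":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 2D/3D TIFF, got ndim={data.ndim}")
    else:
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"{path}: no TIFF slices found")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise FormatError(f"{path}: mixed slice shapes {sorted(shapes)}")
        dtypes = {s.dtype for s in slices}
        if len(dtypes) != 1:
            raise FormatError(f"{path}: mixed slice dtypes {sorted(map(str, dtypes))}")
        data = np.stack(slices)
    if str(data.dtype) not in _SUPPORTED_DTYPES:
        raise FormatError(f"{path}: unsupported dtype {data.dtype}")
    return data


def _write_array(values: np.ndarray, path: str | Path, layout: str) -> None:
    _check_layout(layout)
    if str(values.dtype) not in _SUPPORTED_DTYPES:
        raise FormatError(f"unsupported dtype {values.dtype}")
    path = Path(path)
    if layout == "multipage":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, values)
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(values.shape[0] - 1)))
        for i, page in enumerate(values):
            tifffile.imwrite(path / f"s{i:0{width}d}.tif", page)


def read_volume(
    path: str | Path,
    layout: str = "multipage",
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM,
) -> GrayscaleVolume:
    """Read a grayscale volume from a TIFF stack.

    Values are kept in their stored dtype when float, so that a
    write/read round trip is bit-exact.
    """
    data = _read_array(path, layout)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    return GrayscaleVolume(values=data, voxel_edge_um=voxel_edge_um)


def write_volume(volume: GrayscaleVolume, path: str | Path, layout: str = "multipage") -> None:
    """Write a grayscale volume as 32-bit float TIFF."""
    _write_array(np.asarray(volume.values, dtype=np.float32), path, layout)


def read_mask(
    path: str | Path,
    layout: str = "multipage",
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM,
) -> BinaryVolume:
    """Read a binary mask stored as 8-bit TIFF (0 = solid, 255 = pore)."""
    data = _read_array(path, layout)
    return BinaryVolume(mask=data != SOLID_PIXEL, voxel_edge_um=voxel_edge_um)


def write_mask(binary: BinaryVolume, path: str | Path, layout: str = "multipage") -> None:
    """Write a binary mask as 8-bit TIFF (0 = solid, 255 = pore)."""
    data = np.where(binary.mask, PORE_PIXEL, SOLID_PIXEL).astype(np.uint8)
    _write_array(data, path, layout)
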