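"""Core volumetric data containers.

All volumes are indexed ``(z, y, x)`` (slice, row, column).  The binary
convention throughout the package is ``True`` = pore/void, ``False`` = solid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: Voxel edge length (µm) of the reference scans.
DEFAULT_VOXEL_EDGE_UM = 0.87


@dataclass(frozen=True)
class GrayscaleVolume:
    """3D scalar field of reconstruction intensities.

    Parameters
    ----------
    values : ndarray
        3D float array of dimensionless intensities.
    voxel_edge_um : float
        Edge length of one cubic voxel, in micrometers.
    """

    values: np.ndarray
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3 or min(values.shape) < 1:
            raise InvalidParameterError(
                f"expected a non-empty 3D array, got shape {values.shape}"
            )
        if not self.voxel_edge_um > 0:
            raise InvalidParameterError("voxel_edge_um must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class QuantizedVolume:
    """3D signed 16-bit integer field of quantized intensities."""

    values: np.ndarray
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.dtype != np.int16:
            raise InvalidParameterError(
                f"quantized values must be int16, got {values.dtype}"
            )
        if values.ndim != 3:
            raise InvalidParameterError("quantized volume must be 3D")
        if not self.voxel_edge_um > 0:
            raise InvalidParameterError("voxel_edge_um must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryVolume:
    """3D pore/solid mask; ``True`` marks pore (void) voxels."""

    mask: np.ndarray
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            raise InvalidParameterError(f"mask must be boolean, got {mask.dtype}")
        if mask.ndim != 3 or mask.size < 1:
            raise InvalidParameterError("mask must be a non-empty 3D array")
        if not self.voxel_edge_um > 0:
            raise InvalidParameterError("voxel_edge_um must be positive")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def porosity(self) -> float:
        """Pore-voxel fraction of the whole volume (no size filter)."""
        return float(self.mask.mean())
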