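"""Binarization chain for reconstructed volumes.

The chain reproduces the reference processing of phase-contrast
reconstructions: float intensities are scaled by 100,000 and rounded to
signed 16-bit integers, voxels strictly above the threshold (default 8)
are classed as solid, all but the largest connected solid component is
discarded, and a centered cubic region of interest is cropped.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, InvalidParameterError
from .volumes import BinaryVolume, GrayscaleVolume, QuantizedVolume

__all__ = [
    "SegmentationConfig",
    "quantize",
    "segment",
    "retain_largest_solid",
    "crop_center_roi",
    "segment_volume",
]

DEFAULT_SCALE_FACTOR = 100_000.0
DEFAULT_THRESHOLD = 8
DEFAULT_SOLID_CONNECTIVITY = 26

_INT16_MIN, _INT16_MAX = np.iinfo(np.int16).min, np.iinfo(np.int16).max


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the binarization chain."""

    scale_factor: float = DEFAULT_SCALE_FACTOR
    threshold: int = DEFAULT_THRESHOLD
    solid_connectivity: int = DEFAULT_SOLID_CONNECTIVITY
    roi_edge_vox: int | None = None

    def __post_init__(self) -> None:
        if not self.scale_factor > 0:
            raise InvalidParameterError("scale_factor must be positive")
        if self.solid_connectivity not in (6, 26):
            raise InvalidParameterError("solid_connectivity must be 6 or 26")
        if self.roi_edge_vox is not None and self.roi_edge_vox < 1:
            raise InvalidParameterError("roi_edge_vox must be positive")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise InvalidParameterError(f"connectivity must be 6 or 26, got {connectivity}")


def quantize(
    gray: GrayscaleVolume, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> QuantizedVolume:
    """Scale intensities and round to int16 (half away from zero, clipped)."""
    if not scale_factor > 0:
        raise InvalidParameterError("scale_factor must be positive")
    scaled = np.asarray(gray.values, dtype=np.float64) * scale_factor
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    clipped = np.clip(rounded, _INT16_MIN, _INT16_MAX).astype(np.int16)
    return QuantizedVolume(values=clipped, voxel_edge_um=gray.voxel_edge_um)


def segment(quant: QuantizedVolume, threshold: int = DEFAULT_THRESHOLD) -> BinaryVolume:
    """Class voxels strictly above ``threshold`` as solid, the rest as pore."""
    solid = quant.values > threshold
    return BinaryVolume(mask=~solid, voxel_edge_um=quant.voxel_edge_um)


def retain_largest_solid(
    binary: BinaryVolume, connectivity: int = DEFAULT_SOLID_CONNECTIVITY
) -> BinaryVolume:
    """Keep only the largest connected solid component; the rest becomes pore.

    Ties between equal-sized components are broken toward the component
    containing the first solid voxel in (z, y, x) scan order, which is
    deterministic because labels are assigned in scan order.
    """
    solid = ~binary.mask
    if not solid.any():
        raise DegenerateInputError("volume contains no solid voxels")
    labels, n = ndimage.label(solid, structure=_structure(connectivity))
    if n == 1:
        return binary
    counts = np.bincount(labels.ravel())[1:]
    # argmax returns the lowest label among ties = first in scan order
    keep = int(np.argmax(counts)) + 1
    return BinaryVolume(mask=labels != keep, voxel_edge_um=binary.voxel_edge_um)


def crop_center_roi(binary: BinaryVolume, roi_edge_vox: int) -> BinaryVolume:
    """Crop a centered cube of side ``roi_edge_vox``.

    The start index along each axis is ``floor((dim - edge) / 2)``.
    """
    if roi_edge_vox < 1:
        raise InvalidParameterError("roi_edge_vox must be positive")
    shape = binary.mask.shape
    if any(roi_edge_vox > d for d in shape):
        raise InvalidParameterError(
            f"ROI edge {roi_edge_vox} exceeds volume shape {shape}"
        )
    starts = [(d - roi_edge_vox) // 2 for d in shape]
    sl = tuple(slice(s, s + roi_edge_vox) for s in starts)
    return BinaryVolume(mask=binary.mask[sl].copy(), voxel_edge_um=binary.voxel_edge_um)


def segment_volume(gray: GrayscaleVolume, config: SegmentationConfig) -> BinaryVolume:
    """Run the full chain: quantize → threshold → largest solid → ROI crop."""
    binary = segment(quantize(gray, config.scale_factor), config.threshold)
    binary = retain_largest_solid(binary, config.solid_connectivity)
    if config.roi_edge_vox is not None:
        binary = crop_center_roi(binary, config.roi_edge_vox)
    return binary
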