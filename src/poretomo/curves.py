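"""Per-slice pore frequency curves.

For a chosen axis, the number of pore voxels in every perpendicular slice
is counted, producing the 1D measure analyzed by the multifractal module.
All segmented pore voxels are counted here, regardless of pore size.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .volumes import BinaryVolume

__all__ = ["FrequencyCurve", "pore_frequency_curve", "slice_porosity_range"]


@dataclass(frozen=True)
class FrequencyCurve:
    """Pore-voxel counts per slice along one axis of a volume."""

    counts: np.ndarray
    axis: int
    slice_area_vox: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or len(counts) < 2:
            raise InvalidParameterError("counts must be 1D with at least 2 slices")
        if (counts < 0).any() or (counts > self.slice_area_vox).any():
            raise InvalidParameterError(
                "counts must lie in [0, slice_area_vox]"
            )
        if self.axis not in (0, 1, 2):
            raise InvalidParameterError("axis must be 0, 1 or 2")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"slice": np.arange(self.length), "pore_voxels": self.counts}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def pore_frequency_curve(binary: BinaryVolume, axis: int) -> FrequencyCurve:
    """Count pore voxels in each slice perpendicular to ``axis``."""
    if axis not in (0, 1, 2):
        raise InvalidParameterError("axis must be 0, 1 or 2")
    other = tuple(a for a in range(3) if a != axis)
    counts = binary.mask.sum(axis=other)
    area = int(np.prod([binary.mask.shape[a] for a in other]))
    return FrequencyCurve(counts=counts.astype(np.int64), axis=axis, slice_area_vox=area)


def slice_porosity_range(curve: FrequencyCurve) -> tuple[float, float]:
    """(min, max) per-slice porosity of the curve."""
    return (
        float(curve.counts.min()) / curve.slice_area_vox,
        float(curve.counts.max()) / curve.slice_area_vox,
    )
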