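"""Pore-network metrics from a binary region of interest.

Connected pore components are labelled, their voxel volumes tabulated, and
the summary quantities reported for each sample are computed: total
porosity under a minimum-pore-size rule, the volume fraction of the largest
pore (a connectivity indicator), its 3D-perimeter surface area and
surface-to-volume ratio, the ratio for an equal-volume sphere, and
physical-unit conversions.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, InvalidParameterError
from .volumes import BinaryVolume

__all__ = [
    "PoreLabelField",
    "PoreMetrics",
    "label_pores",
    "total_porosity",
    "largest_pore_fraction",
    "pore_surface_area",
    "surface_to_volume",
    "sphere_equiv_sa_v",
    "physical_volume",
    "equivalent_cube_width",
    "compute_pore_metrics",
]

DEFAULT_PORE_CONNECTIVITY = 26
DEFAULT_MIN_PORE_VOLUME_VOX = 4
#: Volume cutoff below which an isolated pore is narrower than ~3 µm at the
#: reference resolution and considered inaccessible to microbes.
DEFAULT_SMALL_PORE_CUTOFF_VOX = 43


@dataclass(frozen=True)
class PoreLabelField:
    """Labelled pore components of a binary volume.

    ``labels`` uses 0 for solid and dense ids 1..K for pore components in
    scan order of each component's first voxel.  ``volumes[k-1]`` is the
    voxel count of component ``k``.
    """

    labels: np.ndarray
    volumes: np.ndarray
    connectivity: int
    voxel_edge_um: float

    @property
    def n_pores(self) -> int:
        return len(self.volumes)

    @property
    def total_voxels(self) -> int:
        return int(self.labels.size)

    @property
    def pore_voxels(self) -> int:
        return int(self.volumes.sum()) if self.n_pores else 0


@dataclass(frozen=True)
class PoreMetrics:
    """Per-sample summary record."""

    total_porosity: float
    largest_pore_fraction: float
    largest_pore_volume_vox: int
    largest_pore_volume_mm3: float
    largest_pore_sa_v: float
    sphere_equiv_sa_v: float
    n_pores: int
    isolated_small_pore_fraction: float
    pore_connectivity: int
    min_pore_volume_vox: int
    small_pore_cutoff_vox: int
    voxel_edge_um: float

    def to_dict(self) -> dict:
        return asdict(self)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise InvalidParameterError(f"connectivity must be 6 or 26, got {connectivity}")


def label_pores(
    binary: BinaryVolume, connectivity: int = DEFAULT_PORE_CONNECTIVITY
) -> PoreLabelField:
    """Label connected pore components under 6- or 26-connectivity."""
    labels, n = ndimage.label(binary.mask, structure=_structure(connectivity))
    volumes = np.bincount(labels.ravel(), minlength=n + 1)[1:] if n else np.zeros(0, int)
    return PoreLabelField(
        labels=labels,
        volumes=volumes.astype(np.int64),
        connectivity=connectivity,
        voxel_edge_um=binary.voxel_edge_um,
    )


def total_porosity(
    labels: PoreLabelField, min_volume_vox: int = DEFAULT_MIN_PORE_VOLUME_VOX
) -> float:
    """Pore fraction of the ROI counting only pores of at least
    ``min_volume_vox`` voxels."""
    if min_volume_vox < 1:
        raise InvalidParameterError("min_volume_vox must be >= 1")
    if labels.n_pores == 0:
        return 0.0
    kept = labels.volumes[labels.volumes >= min_volume_vox]
    return float(kept.sum()) / labels.total_voxels


def largest_pore_fraction(labels: PoreLabelField) -> float:
    """Largest pore volume over total pore volume (no size filter)."""
    if labels.n_pores == 0:
        raise DegenerateInputError("no pore components")
    return float(labels.volumes.max()) / float(labels.volumes.sum())


def pore_surface_area(mask: np.ndarray) -> int:
    """3D perimeter of a pore mask: pore voxels with a face-adjacent
    non-pore neighbor, the volume boundary counting as non-pore."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty pore mask")
    padded = np.pad(mask, 1, constant_values=False)
    interior = np.ones_like(mask)
    for axis in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[axis] = slice(0, -2)
        hi[axis] = slice(2, None)
        interior &= padded[tuple(lo)] & padded[tuple(hi)]
    return int(np.count_nonzero(mask & ~interior))


def surface_to_volume(mask: np.ndarray) -> float:
    """Perimeter voxel count divided by pore voxel count."""
    mask = np.asarray(mask, dtype=bool)
    return pore_surface_area(mask) / int(np.count_nonzero(mask))


def sphere_equiv_sa_v(volume_vox: float) -> float:
    """Surface-to-volume ratio 3/r of a continuum sphere of equal volume."""
    if not volume_vox > 0:
        raise InvalidParameterError("volume_vox must be positive")
    radius = (3.0 * volume_vox / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 3.0 / radius


def physical_volume(voxels: float, voxel_edge_um: float) -> float:
    """Convert a voxel count to mm³."""
    if not voxel_edge_um > 0:
        raise InvalidParameterError("voxel_edge_um must be positive")
    return float(voxels) * (voxel_edge_um * 1e-3) ** 3


def equivalent_cube_width(volume_vox: float, voxel_edge_um: float) -> float:
    """Edge length in µm of a cube with the given voxel volume."""
    if volume_vox < 0:
        raise InvalidParameterError("volume_vox must be non-negative")
    return float(volume_vox) ** (1.0 / 3.0) * voxel_edge_um


def compute_pore_metrics(
    binary: BinaryVolume,
    connectivity: int = DEFAULT_PORE_CONNECTIVITY,
    min_pore_volume_vox: int = DEFAULT_MIN_PORE_VOLUME_VOX,
    small_pore_cutoff_vox: int = DEFAULT_SMALL_PORE_CUTOFF_VOX,
) -> PoreMetrics:
    """Compute the full per-sample metric record for a binary ROI."""
    field = label_pores(binary, connectivity)
    if field.n_pores == 0:
        raise DegenerateInputError("volume contains no pore voxels")
    largest = int(np.argmax(field.volumes)) + 1
    largest_vol = int(field.volumes[largest - 1])
    sa_v = surface_to_volume(field.labels == largest)
    others = np.delete(field.volumes, largest - 1)
    small_frac = (
        float(np.count_nonzero(others < small_pore_cutoff_vox)) / len(others)
        if len(others)
        else float("nan")
    )
    return PoreMetrics(
        total_porosity=total_porosity(field, min_pore_volume_vox),
        largest_pore_fraction=largest_pore_fraction(field),
        largest_pore_volume_vox=largest_vol,
        largest_pore_volume_mm3=physical_volume(largest_vol, binary.voxel_edge_um),
        largest_pore_sa_v=sa_v,
        sphere_equiv_sa_v=sphere_equiv_sa_v(largest_vol),
        n_pores=field.n_pores,
        isolated_small_pore_fraction=small_frac,
        pore_connectivity=connectivity,
        min_pore_volume_vox=min_pore_volume_vox,
        small_pore_cutoff_vox=small_pore_cutoff_vox,
        voxel_edge_um=binary.voxel_edge_um,
    )
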