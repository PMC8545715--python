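"""Synthetic test volumes and 1D measures with known multifractal spectra.

Two phantom families stand in for scanned pellet char:

* ``fragment_pack`` — overlapping, randomly oriented solid ellipsoids
  deposited until a target solid fraction is reached; statistically
  isotropic, mimicking a disordered packing of crushed wood fragments.
* ``tube_array`` — a solid block pierced by a regular grid of parallel
  cylindrical pores; strongly anisotropic, mimicking tracheid lumina.

Binomial multiplicative cascades provide 1D measures whose singularity and
Rényi spectra are known in closed form, used as oracles for the
multifractal estimators.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidParameterError
from .volumes import BinaryVolume, GrayscaleVolume, DEFAULT_VOXEL_EDGE_UM

__all__ = [
    "CascadeParams",
    "PhantomSpec",
    "generate_binomial_cascade",
    "cascade_true_spectrum",
    "generate_phantom",
    "render_grayscale",
]

#: Default grayscale levels: after quantization with the default scale factor
#: (1e5) the solid maps to ~20, comfortably above the default threshold 8.
DEFAULT_SOLID_LEVEL = 2e-4
DEFAULT_PORE_LEVEL = 0.0


@dataclass(frozen=True)
class CascadeParams:
    """Parameters of a deterministic binomial multiplicative cascade.

    ``p`` is the mass fraction sent to the left half at every dyadic
    refinement; ``depth`` is the number of refinement levels, giving
    ``2**depth`` bins.  When ``shuffle_seed`` is set the final bins are
    permuted with a seeded RNG (the spectrum of the measure's value
    distribution is unchanged; its dyadic arrangement is destroyed).
    """

    p: float
    depth: int
    shuffle_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise InvalidParameterError(f"p must be in (0, 1), got {self.p}")
        if self.depth < 1:
            raise InvalidParameterError(f"depth must be >= 1, got {self.depth}")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic binary porous volume."""

    shape: tuple[int, int, int]
    target_porosity: float
    structure: Literal["fragment_pack", "tube_array"]
    seed: int = 0
    tube_axis: int = 0
    tube_radius_vox: float = 4.0
    tube_spacing_vox: float = 16.0
    fragment_size_vox: float = 12.0
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise InvalidParameterError(
                f"shape must be three integers >= 8, got {self.shape}"
            )
        if not 0.0 <= self.target_porosity <= 1.0:
            raise InvalidParameterError(
                f"target_porosity must be in [0, 1], got {self.target_porosity}"
            )
        if self.structure not in ("fragment_pack", "tube_array"):
            raise InvalidParameterError(f"unknown structure {self.structure!r}")
        if self.structure == "tube_array":
            if self.tube_axis not in (0, 1, 2):
                raise InvalidParameterError("tube_axis must be 0, 1 or 2")
            if self.tube_radius_vox <= 0 or self.tube_spacing_vox <= 0:
                raise InvalidParameterError("tube radius and spacing must be positive")
            if not self.tube_radius_vox < self.tube_spacing_vox / 2:
                raise InvalidParameterError(
                    "tube_radius_vox must be < tube_spacing_vox / 2"
                )
        elif self.fragment_size_vox <= 0:
            raise InvalidParameterError("fragment_size_vox must be positive")


def generate_binomial_cascade(params: CascadeParams) -> np.ndarray:
    """Return the ``2**depth`` bin weights of a binomial cascade.

    Bin ``i`` carries the product, over refinement levels, of ``p`` for a 0
    bit and ``1 - p`` for a 1 bit in the binary expansion of ``i`` (most
    significant bit first).  Weights sum to 1 exactly up to float rounding.
    """
    w = np.array([1.0])
    step = np.array([params.p, 1.0 - params.p])
    for _ in range(params.depth):
        w = np.kron(w, step)
    if params.shuffle_seed is not None:
        rng = np.random.default_rng(params.shuffle_seed)
        w = rng.permutation(w)
    return w


def cascade_true_spectrum(
    p: float, q: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form ``(D_q, alpha_q, f_q)`` of the binomial cascade.

    For ``q != 1``::

        D_q = -log2(p**q + (1-p)**q) / (q - 1)

    with the entropy limit at ``q = 1``.  ``alpha_q`` is the weighted mean
    Hölder exponent and ``f_q = q * alpha_q - (q - 1) * D_q``.
    Accepts scalar or array ``q``; returns arrays of the same shape.
    """
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"p must be in (0, 1), got {p}")
    q = np.asarray(q, dtype=float)
    r = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        z = p**q + r**q
        d = -np.log2(z) / (q - 1.0)
    d1 = -(p * np.log2(p) + r * np.log2(r))
    d = np.where(np.isclose(q, 1.0), d1, d)
    alpha = -(p**q * np.log2(p) + r**q * np.log2(r)) / z
    f = q * alpha - (q - 1.0) * d
    return d, alpha, f


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random 3D rotation matrix from a normalized quaternion."""
    quat = rng.normal(size=4)
    w, x, y, z = quat / np.linalg.norm(quat)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _deposit_ellipsoid(
    solid: np.ndarray, center: np.ndarray, semi: np.ndarray, rot: np.ndarray
) -> int:
    """Set voxels inside a rotated ellipsoid to solid; return voxels added."""
    radius = float(semi.max())
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, solid.shape)
    if np.any(lo >= hi):
        return 0
    grids = np.meshgrid(
        *(np.arange(lo[a], hi[a], dtype=float) for a in range(3)), indexing="ij"
    )
    rel = np.stack([g - c for g, c in zip(grids, center)])
    local = np.einsum("ij,j...->i...", rot.T, rel)
    inside = (
        (local[0] / semi[0]) ** 2
        + (local[1] / semi[1]) ** 2
        + (local[2] / semi[2]) ** 2
    ) <= 1.0
    sub = solid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    added = int(np.count_nonzero(inside & ~sub))
    sub |= inside
    return added


def _fragment_pack(spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    solid = np.zeros(shape, dtype=bool)
    total = solid.size
    target_solid = round((1.0 - spec.target_porosity) * total)
    n_solid = 0
    base = spec.fragment_size_vox / 2.0
    # Deposition stops at the first ellipsoid crossing the target count, so
    # the porosity lands slightly below target (within one fragment volume).
    max_iter = 100 * total // max(int(base**3), 1) + 1000
    it = 0
    while n_solid < target_solid:
        it += 1
        if it > max_iter:
            raise InvalidParameterError(
                "fragment deposition failed to reach target porosity "
                f"{spec.target_porosity} within {max_iter} iterations"
            )
        center = rng.uniform(0.0, np.array(shape, dtype=float))
        semi = base * rng.uniform(0.6, 1.5, size=3)
        n_solid += _deposit_ellipsoid(solid, center, semi, _random_rotation(rng))
    return ~solid  # pore mask


def _tube_array(spec: PhantomSpec) -> np.ndarray:
    shape = tuple(int(s) for s in spec.shape)
    axis = spec.tube_axis
    perp = [a for a in range(3) if a != axis]
    s = spec.tube_spacing_vox
    r2 = spec.tube_radius_vox**2
    cross = np.zeros((shape[perp[0]], shape[perp[1]]), dtype=bool)
    n0 = int(shape[perp[0]] // s)
    n1 = int(shape[perp[1]] // s)
    if n0 < 1 or n1 < 1:
        raise InvalidParameterError("tube_spacing_vox exceeds volume cross-section")
    yy, xx = np.meshgrid(
        np.arange(shape[perp[0]], dtype=float),
        np.arange(shape[perp[1]], dtype=float),
        indexing="ij",
    )
    for i in range(n0):
        cy = i * s + s / 2.0 - 0.5
        for j in range(n1):
            cx = j * s + s / 2.0 - 0.5
            cross |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r2
    # expand_dims re-inserts the tube axis at its original position, so the
    # remaining axes are already in (z, y, x) order
    return np.broadcast_to(np.expand_dims(cross, axis=axis), shape).copy()


def generate_phantom(spec: PhantomSpec) -> BinaryVolume:
    """Build the binary phantom described by ``spec`` (True = pore).

    ``fragment_pack`` porosity is controlled by a stopping rule and is
    accurate to about ±0.02; ``tube_array`` ignores ``target_porosity``
    (porosity follows from radius and spacing).  Reproducible for a fixed
    ``spec.seed``.
    """
    if spec.structure == "fragment_pack":
        if spec.target_porosity >= 1.0:
            mask = np.ones(tuple(int(s) for s in spec.shape), dtype=bool)
        else:
            mask = _fragment_pack(spec)
    else:
        mask = _tube_array(spec)
    return BinaryVolume(mask=mask, voxel_edge_um=spec.voxel_edge_um)


def render_grayscale(
    binary: BinaryVolume,
    solid_level: float = DEFAULT_SOLID_LEVEL,
    pore_level: float = DEFAULT_PORE_LEVEL,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrayscaleVolume:
    """Render a binary mask as a noisy grayscale reconstruction.

    Each voxel gets its class level (solid brighter than pore) plus
    i.i.d. Gaussian noise of standard deviation ``noise_sd``.
    """
    if not solid_level > pore_level:
        raise InvalidParameterError("solid_level must exceed pore_level")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    values = np.where(binary.mask, pore_level, solid_level).astype(np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return GrayscaleVolume(
        values=values.astype(np.float32), voxel_edge_um=binary.voxel_edge_um
    )
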