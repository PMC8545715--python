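import numpy as np
import pytest

from poretomo import BinaryVolume, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def fragment_volume_128():
    """Isotropic fragment-packed phantom at the reference porosity."""
    spec = PhantomSpec(
        shape=(128, 128, 128),
        target_porosity=0.577,
        structure="fragment_pack",
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def tube_volume_128():
    """Anisotropic tube phantom with tubes along axis 0."""
    spec = PhantomSpec(
        shape=(128, 128, 128),
        target_porosity=0.2,
        structure="tube_array",
        tube_axis=0,
        tube_radius_vox=4.0,
        tube_spacing_vox=16.0,
        seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture
def random_mask_factory():
    """Small random binary volumes for oracle comparisons."""

    def make(seed: int, shape=(8, 8, 8), p_pore: float = 0.4) -> BinaryVolume:
        rng = np.random.default_rng(seed)
        return BinaryVolume(mask=rng.random(shape) < p_pore)

    return make


def digitized_ball(radius: int) -> np.ndarray:
    """Boolean mask of a ball of the given radius, centered in a tight box."""
    n = 2 * radius + 3
    c = (n - 1) / 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def brute_force_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Reference flood-fill labelling, independent of scipy.ndimage.

    Components are numbered in scan order of their first voxel.
    """
    if connectivity == 6:
        offsets = [
            (dz, dy, dx)
            for dz, dy, dx in (
                (-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1),
            )
        ]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for idx in np.ndindex(mask.shape):
        if not mask[idx] or labels[idx]:
            continue
        current += 1
        stack = [idx]
        labels[idx] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not labels[nz, ny, nx]
                ):
                    labels[nz, ny, nx] = current
                    stack.append((nz, ny, nx))
    return labels


def brute_force_perimeter(mask: np.ndarray) -> int:
    """Reference 3D perimeter count by explicit neighbor checks."""
    count = 0
    shape = mask.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        z, y, x = idx
        for dz, dy, dx in (
            (-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1),
        ):
            nz, ny, nx = z + dz, y + dy, x + dx
            outside = not (
                0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]
            )
            if outside or not mask[nz, ny, nx]:
                count += 1
                break
    return count
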