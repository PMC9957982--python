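"""Shared fixtures: nomenclature, voxel phantoms, small synthetic trees."""

from __future__ import annotations

import numpy as np
import pytest

from arterylabel import NomenclatureMap, VoxelVolume


@pytest.fixture(scope="session")
def nmap() -> NomenclatureMap:
    return NomenclatureMap.default()


def make_cylinder(
    radius_mm: float = 2.0,
    length_mm: float = 40.0,
    spacing=0.28,
    pad: int = 4,
    centre_offset: float = 0.25,
) -> VoxelVolume:
    """Solid cylinder along z; the small centre offset avoids perfectly
    voxel-symmetric degeneracy.  ``spacing`` may be anisotropic."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    nx = int(np.ceil(2 * radius_mm / spacing[0])) + 2 * pad
    ny = int(np.ceil(2 * radius_mm / spacing[1])) + 2 * pad
    nz = int(np.ceil(length_mm / spacing[2])) + 2 * pad
    cx = ((nx - 1) / 2 + centre_offset) * spacing[0]
    cy = ((ny - 1) / 2 + centre_offset) * spacing[1]
    X, Y = np.meshgrid(
        np.arange(nx) * spacing[0], np.arange(ny) * spacing[1], indexing="ij"
    )
    disk = (X - cx) ** 2 + (Y - cy) ** 2 <= radius_mm**2
    occ = np.zeros((nx, ny, nz), dtype=bool)
    occ[:, :, pad : nz - pad] = disk[:, :, None]
    return VoxelVolume(occ, spacing)


def make_tube_from_points(pts: np.ndarray, radius_mm: float,
                          spacing: float = 0.28) -> VoxelVolume:
    """Voxelised constant-radius tube around a dense point set."""
    from scipy.spatial import cKDTree

    lo = pts.min(axis=0) - radius_mm - 1.0
    hi = pts.max(axis=0) + radius_mm + 1.0
    shape = np.ceil((hi - lo) / spacing).astype(int)
    grid = np.stack(
        np.meshgrid(*[lo[a] + np.arange(shape[a]) * spacing for a in range(3)],
                    indexing="ij"),
        axis=-1,
    )
    d, _ = cKDTree(pts).query(grid.reshape(-1, 3))
    occ = (d <= radius_mm).reshape(tuple(shape))
    return VoxelVolume(occ, spacing, lo)


@pytest.fixture(scope="session")
def cylinder() -> VoxelVolume:
    """r = 2.0 mm, L = 40 mm cylinder at 0.28 mm isotropic spacing."""
    return make_cylinder()


@pytest.fixture(scope="session")
def y_phantom() -> VoxelVolume:
    """Y-shaped tube: one trunk splitting into two arms, r = 1.5 mm."""
    pts = []
    for t in np.linspace(0, 20, 150):
        pts.append((15.0, 15.0, t))
    for t in np.linspace(0, 16, 120):
        pts.append((15.0 + t * 0.707, 15.0, 20.0 + t * 0.707))
        pts.append((15.0 - t * 0.707, 15.0, 20.0 + t * 0.707))
    return make_tube_from_points(np.array(pts), 1.5)


@pytest.fixture(scope="session")
def torus() -> VoxelVolume:
    """Torus tube (ring radius 8 mm, tube radius 1.2 mm)."""
    spacing = 0.3
    R, r = 8.0, 1.2
    n = int(np.ceil((2 * (R + r) + 4) / spacing))
    x = (np.arange(n) - n / 2 + 0.3) * spacing
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    occ = (np.sqrt(X**2 + Y**2) - R) ** 2 + Z**2 <= r**2
    return VoxelVolume(occ, spacing)
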