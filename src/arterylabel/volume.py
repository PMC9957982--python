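"""Raster containers for binary angiographic volumes and label maps.

Conventions used throughout the package: arrays are indexed ``[i, j, k]``
mapping to world axes ``(x, y, z)``; world coordinates are millimetres in a
right-handed frame; voxel ``(0, 0, 0)`` has its *centre* at ``origin_mm``;
"slice" means a plane of constant ``k`` (constant z), so the inferior-most
slice is ``k = 0`` territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

BACKGROUND = -1  # sentinel in LabelVolume.labels


def _as_triple(x) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,)).copy()
    return arr


@dataclass
class VoxelVolume:
    """3-D binary occupancy grid with voxel spacing and world origin."""

    occupancy: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3-D array")
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be strictly positive")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def foreground_mm3(self) -> float:
        return float(self.occupancy.sum()) * self.voxel_volume_mm3

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing_mm, self.spacing_mm[0], rtol=1e-6))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing_mm + self.origin_mm

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin_mm) / self.spacing_mm

    # ------------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(np.append(self.spacing_mm, 1.0))
        affine[:3, 3] = self.origin_mm
        return nib.Nifti1Image(self.occupancy.astype(np.uint8), affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls(data > 0, spacing, origin)


@dataclass
class LabelVolume:
    """Per-voxel branch-code map sharing grid and spacing with its volume.

    ``labels`` stores integer indices into ``codes``; background voxels hold
    :data:`BACKGROUND`.
    """

    labels: np.ndarray
    codes: list[str]
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)

    @property
    def shape(self):
        return self.labels.shape

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin_mm) / self.spacing_mm

    def code_at(self, idx) -> str | None:
        v = self.labels[tuple(idx)]
        return None if v == BACKGROUND else self.codes[v]

    def present_codes(self) -> list[str]:
        present = np.unique(self.labels)
        return [self.codes[v] for v in present if v != BACKGROUND]

    def save(self, path: str | Path) -> None:
        affine = np.diag(np.append(self.spacing_mm, 1.0))
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image((self.labels + 1).astype(np.int16), affine)
        img.header["descrip"] = b"labels are 1-based; 0 = background"
        nib.save(img, str(path))

    def save_codes(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.codes, indent=0))

    @classmethod
    def load(cls, path: str | Path, codes: list[str]) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.int16) - 1
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return cls(data, codes, spacing, origin)
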