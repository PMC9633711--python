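"""Reference grid and volume containers.

All stages of the pipeline operate on a single common grid (the stand-in
for a normalized template space): lesion masks, disconnection severity
maps and statistical maps are plain 3-D arrays tied to one
:class:`ReferenceGrid`.  NIfTI-1 is the on-disk format throughout; the
grid's affine maps *voxel-box corners* to world millimetres, i.e. voxel
``v`` occupies the half-open box ``[v, v + 1)`` in voxel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ReferenceGrid", "VolumeImage"]


@dataclass(frozen=True)
class ReferenceGrid:
    """A 3-D voxel grid with a voxel-to-world affine.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; every entry must be >= 8.
    voxel_size : tuple of float
        Edge length of a voxel in mm per axis; all entries > 0.
    origin : tuple of float
        World coordinate of the corner of voxel (0, 0, 0), in mm.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError("grid shape must be three entries, each >= 8")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world transform (diagonal scaling + origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world-mm corners of the grid's bounding box."""
        lo = np.asarray(self.origin, float)
        hi = lo + np.asarray(self.shape, float) * np.asarray(self.voxel_size, float)
        return lo, hi

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, float))
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, voxel_coords: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(voxel_coords, float))
        aff = self.affine
        return pts @ aff[:3, :3].T + aff[:3, 3]

    def new_volume(self, dtype=np.float64) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)


@dataclass
class VolumeImage:
    """A scalar 3-D volume on a :class:`ReferenceGrid`.

    Thin carrier used for lesion masks, severity maps and Z maps; data
    is a plain ndarray so numpy operations apply directly.
    """

    data: np.ndarray
    grid: ReferenceGrid
    name: str = field(default="")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"volume shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asanyarray(self.data), self.grid.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, grid: ReferenceGrid | None = None) -> "VolumeImage":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if grid is None:
            aff = img.affine
            grid = ReferenceGrid(
                shape=tuple(int(s) for s in data.shape),
                voxel_size=tuple(float(v) for v in np.diag(aff)[:3]),
                origin=tuple(float(v) for v in aff[:3, 3]),
            )
        return cls(data=data, grid=grid, name=str(path))
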