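"""NIfTI volume I/O, image grids, affines, and brain masks.

All spatial bookkeeping goes through a 4x4 voxel-to-mm affine, so any
orientation a NIfTI header declares is handled uniformly.  Voxel indices are
0-based; user-facing reports are in stereotaxic mm, matching the convention
of seed-based connectivity studies that report Talairach peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ImageGrid",
    "Bold4D",
    "BrainMask",
    "StatMap",
    "read_volume",
    "read_mask",
    "write_volume",
    "mm_to_voxel",
    "voxel_to_mm",
    "auto_brain_mask",
]


@dataclass(frozen=True)
class ImageGrid:
    """A 3D sampling grid with a voxel-index -> stereotaxic-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4, homogeneous voxel -> mm

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if not np.all(np.isfinite(aff)):
            raise ValueError("affine contains non-finite entries")
        if any(d < 1 for d in dims):
            raise ValueError(f"grid dims must all be >= 1, got {dims}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine upper-left 3x3 is singular")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def standard(
        cls, dims: tuple[int, int, int], voxel_size_mm: float = 3.0
    ) -> "ImageGrid":
        """Axis-aligned RAS+ grid with the mm origin at the grid centre."""
        dims = tuple(int(d) for d in dims)
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
        aff[:3, 3] = -voxel_size_mm * (np.asarray(dims) - 1) / 2.0
        return cls(dims, aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre mm coordinates."""
        idx = np.indices(self.dims).reshape(3, -1)
        mm = self.affine[:3, :3] @ idx + self.affine[:3, 3:4]
        return mm.T.reshape(*self.dims, 3)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageGrid):
            return NotImplemented
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def __hash__(self) -> int:
        return hash((self.dims, self.affine.tobytes()))


def voxel_to_mm(grid: ImageGrid, ijk) -> np.ndarray:
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    mm = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return mm[0] if mm.shape[0] == 1 else mm


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def mm_to_voxel(grid: ImageGrid, mm) -> tuple[int, int, int]:
    """Nearest voxel index of an mm coordinate.

    Ties round half away from zero per axis (deterministic).  Raises if the
    coordinate falls outside the grid bounds.
    """
    mm = np.asarray(mm, dtype=float)
    inv = np.linalg.inv(grid.affine)
    cont = inv[:3, :3] @ mm + inv[:3, 3]
    idx = _round_half_away(cont).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.dims)):
        raise ValueError(
            f"mm coordinate {tuple(mm)} maps to voxel {tuple(idx)} "
            f"outside grid dims {grid.dims}"
        )
    return tuple(int(i) for i in idx)


@dataclass
class Bold4D:
    """One subject-session's 4D BOLD volume (space x time)."""

    grid: ImageGrid
    data: np.ndarray  # (nx, ny, nz, T)
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 3D or 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match grid {self.grid.dims}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Boolean voxel-inclusion mask on a grid."""

    grid: ImageGrid
    included: np.ndarray

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.included.shape} does not match grid {self.grid.dims}"
            )
        if not self.included.any():
            raise ValueError("mask is empty (no included voxels)")

    @property
    def n_voxels(self) -> int:
        return int(self.included.sum())

    def __and__(self, other: "BrainMask") -> "BrainMask":
        if self.grid != other.grid:
            raise ValueError("masks live on different grids")
        return BrainMask(self.grid, self.included & other.included)


@dataclass
class StatMap:
    """Per-voxel statistic map (t, F, r or z) with degrees of freedom."""

    grid: ImageGrid
    data: np.ndarray  # 3D
    stat_type: str = "t"  # one of {"t", "F", "r", "z"}
    df: tuple | int | None = None
    mask: BrainMask | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"stat data shape {self.data.shape} does not match grid {self.grid.dims}"
            )
        if self.stat_type not in {"t", "F", "r", "z"}:
            raise ValueError(f"unknown stat_type {self.stat_type!r}")
        inside = self.data if self.mask is None else self.data[self.mask.included]
        if not np.all(np.isfinite(inside)):
            raise ValueError("statistic map contains non-finite values inside mask")


def read_volume(path, tr_seconds: float = 2.0) -> Bold4D:
    """Read a 3D or 4D NIfTI-1 file; 3D files yield a single-timepoint volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
    except Exception as exc:  # nibabel raises various types on bad payloads
        raise ValueError(f"{path} is not a readable NIfTI volume: {exc}") from exc
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)):
        raise ValueError(f"{path} declares a non-finite affine")
    if data.ndim not in (3, 4):
        raise ValueError(f"{path} is {data.ndim}D; expected a 3D or 4D volume")
    grid = ImageGrid(tuple(data.shape[:3]), affine)
    zooms = img.header.get_zooms()
    if data.ndim == 4 and len(zooms) >= 4 and zooms[3] > 0:
        tr_seconds = float(zooms[3])
    return Bold4D(grid, data, tr_seconds=tr_seconds)


def read_mask(path) -> BrainMask:
    vol = read_volume(path)
    return BrainMask(vol.grid, vol.data[..., 0] > 0)


def write_volume(path, obj) -> Path:
    """Write a Bold4D / StatMap / BrainMask / FCMap as float32 NIfTI-1."""
    path = Path(path)
    if isinstance(obj, Bold4D):
        grid, data = obj.grid, obj.data
        if data.shape[3] == 1:
            data = data[..., 0]
    elif isinstance(obj, BrainMask):
        grid, data = obj.grid, obj.included.astype(np.float32)
    elif isinstance(obj, StatMap):
        grid, data = obj.grid, obj.data
    elif hasattr(obj, "z") and hasattr(obj, "grid"):  # FCMap duck-typed
        grid, data = obj.grid, obj.z
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    if isinstance(obj, Bold4D):
        zooms = list(img.header.get_zooms())
        if len(zooms) == 4:
            zooms[3] = obj.tr_seconds
            img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def auto_brain_mask(bold: Bold4D, fraction: float = 0.5) -> BrainMask:
    """Threshold the temporal-mean image at ``fraction`` x its grand mean.

    A simple intensity-based foreground mask: a voxel is brain if its mean
    signal is at least ``fraction`` times the mean over all voxels.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    tmean = bold.data.mean(axis=3)
    grand = tmean.mean()
    if grand == 0 and not tmean.any():
        raise ValueError("cannot mask an all-zero volume")
    included = tmean >= fraction * grand
    if not included.any():
        raise ValueError("auto mask came out empty; lower the fraction")
    return BrainMask(bold.grid, included)
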