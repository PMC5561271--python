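"""Bilateral amygdala seed construction and Fisher-z connectivity maps.

The seed is a pair of 5 mm spheres centred on the left/right amygdala
(Talairach +/-22, -6, -14).  Because left and right amygdala time courses are
highly correlated, the two sphere means are averaged into one seed course,
which is then Pearson-correlated with every brain voxel; correlations are
variance-stabilized with Fisher's z = atanh(r).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume_io import Bold4D, BrainMask, ImageGrid, mm_to_voxel

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSpec",
    "FCMap",
    "DEFAULT_SEED",
    "build_sphere_mask",
    "extract_seed_course",
    "fc_map",
]

#: |r| is clipped here before atanh so self-correlated voxels stay finite.
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """Left/right sphere centres (mm) and a common radius."""

    left_mm: tuple[float, float, float] = (-22.0, -6.0, -14.0)
    right_mm: tuple[float, float, float] = (22.0, -6.0, -14.0)
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")

    def masks(self, grid: ImageGrid) -> tuple[BrainMask, BrainMask]:
        return (
            build_sphere_mask(grid, self.left_mm, self.radius_mm),
            build_sphere_mask(grid, self.right_mm, self.radius_mm),
        )


DEFAULT_SEED = SeedSpec()


@dataclass
class FCMap:
    """One subject-session's Fisher-z amygdala connectivity map."""

    grid: ImageGrid
    z: np.ndarray  # 3D, zero outside mask
    subject_id: str = ""
    session: str = ""
    mask: BrainMask | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != self.grid.dims:
            raise ValueError("z map shape does not match grid")
        inside = self.z if self.mask is None else self.z[self.mask.included]
        if not np.all(np.isfinite(inside)):
            raise ValueError("z map contains non-finite values inside mask")


def build_sphere_mask(grid: ImageGrid, center_mm, radius_mm: float) -> BrainMask:
    """Voxels whose centre lies within ``radius_mm`` of ``center_mm``."""
    mm_to_voxel(grid, center_mm)  # bounds check, raises with the coordinate
    centers = grid.voxel_centers_mm()
    d2 = ((centers - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=-1)
    included = d2 <= float(radius_mm) ** 2
    if not included.any():
        raise ValueError(
            f"sphere of radius {radius_mm} mm at {tuple(center_mm)} contains no "
            "voxel centre; enlarge the radius or fall back to the nearest voxel "
            f"{mm_to_voxel(grid, center_mm)}"
        )
    return BrainMask(grid, included)


def extract_seed_course(bold: Bold4D, left: BrainMask, right: BrainMask) -> np.ndarray:
    """Average of the left- and right-sphere mean time courses."""
    for m in (left, right):
        if m.grid != bold.grid:
            raise ValueError("seed mask grid does not match BOLD grid")
    course = 0.5 * (
        bold.data[left.included].mean(axis=0) + bold.data[right.included].mean(axis=0)
    )
    if np.ptp(course) == 0:
        raise ValueError("seed time course is constant (zero variance)")
    return course


def fc_map(
    bold: Bold4D,
    seed_course: np.ndarray,
    mask: BrainMask | None = None,
    confounds: np.ndarray | None = None,
    subject_id: str = "",
    session: str = "",
) -> FCMap:
    """Whole-brain Fisher-z map of voxel-vs-seed Pearson correlation.

    Zero-variance voxels get z = 0 with a logged warning.  ``confounds``
    (T x q), if given, are residualized out of both the seed course and every
    voxel course before correlating; the study's preprocessing details are
    not modelled here, so the default is no confounds.
    """
    seed_course = np.asarray(seed_course, dtype=float)
    if seed_course.ndim != 1 or seed_course.size != bold.n_timepoints:
        raise ValueError(
            f"seed course length {seed_course.size} does not match "
            f"{bold.n_timepoints} timepoints"
        )
    if mask is None:
        mask = BrainMask(bold.grid, np.ones(bold.grid.dims, dtype=bool))
    elif mask.grid != bold.grid:
        raise ValueError("mask grid does not match BOLD grid")

    x = np.asarray(bold.data[mask.included], dtype=np.float64)  # (V, T)
    s = seed_course.copy()
    if confounds is not None:
        c = np.column_stack([np.ones(bold.n_timepoints), np.asarray(confounds, float)])
        beta_s, *_ = np.linalg.lstsq(c, s, rcond=None)
        s = s - c @ beta_s
        beta_x, *_ = np.linalg.lstsq(c, x.T, rcond=None)
        x = x - (c @ beta_x).T
    if np.ptp(s) == 0:
        raise ValueError("seed course has zero variance")

    s = s - s.mean()
    s /= np.linalg.norm(s)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        logger.warning(
            "%d voxels have zero temporal variance; their z is set to 0",
            int(degenerate.sum()),
        )
        norms[degenerate] = 1.0
    r = (x / norms[:, np.newaxis]) @ s
    r[degenerate] = 0.0
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))

    zvol = np.zeros(bold.grid.dims)
    zvol[mask.included] = z
    return FCMap(bold.grid, zvol, subject_id=subject_id, session=session, mask=mask)
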