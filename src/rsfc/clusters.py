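"""Cluster-extent family-wise error control by Monte-Carlo simulation.

Suprathreshold voxels are grouped into 3D connected components; the minimum
cluster size that keeps the family-wise error at alpha is taken from the
max-cluster-size distribution of simulated smooth Gaussian null fields,
matched to the data's spatial smoothness (AlphaSim-style correction).
Smoothness is summarized as a per-axis Gaussian-kernel FWHM obtained from
the variance of neighbouring-voxel differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume_io import BrainMask, ImageGrid, StatMap

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothnessEstimate",
    "ExtentNull",
    "ClusterTable",
    "label_clusters",
    "estimate_smoothness",
    "extent_threshold",
    "apply_extent",
    "connectivity_structure",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 neighbourhood footprint for 6-, 18- or 26-connectivity."""
    try:
        order = {6: 1, 18: 2, 26: 3}[int(connectivity)]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, order)


@dataclass(frozen=True)
class SmoothnessEstimate:
    """Per-axis Gaussian-kernel-equivalent FWHM in mm."""

    fwhm_mm: tuple[float, float, float]
    method: str = "gradient-variance"

    @property
    def mean_fwhm_mm(self) -> float:
        return float(np.mean(self.fwhm_mm))


@dataclass
class ExtentNull:
    """Monte-Carlo max-cluster-size null and the derived critical extent."""

    iterations: int
    voxel_p: float
    alpha: float
    connectivity: int
    two_tailed: bool
    max_size_counts: np.ndarray  # counts per size, index = size in voxels
    critical_extent_k: int
    rng_seed: int

    def cluster_p(self, size_voxels: int) -> float:
        """Empirical cluster-level p: P(max null cluster >= size)."""
        sizes = np.arange(len(self.max_size_counts))
        return float(
            self.max_size_counts[sizes >= size_voxels].sum() / self.iterations
        )


@dataclass
class ClusterTable:
    """Labelled suprathreshold clusters of a statistic map."""

    grid: ImageGrid
    labels: np.ndarray  # 3D int, 0 = background
    df: pd.DataFrame  # label, size_voxels, size_mm3, peak_value, peak mm, sign
    threshold: float
    connectivity: int
    two_tailed: bool
    voxel_p: float | None = None

    def __len__(self) -> int:
        return len(self.df)

    def cluster_mask(self, label: int) -> BrainMask:
        return BrainMask(self.grid, self.labels == label)

    def with_df(self, df: pd.DataFrame) -> "ClusterTable":
        keep = set(df.label)
        labels = np.where(np.isin(self.labels, list(keep)), self.labels, 0)
        return replace(self, labels=labels, df=df.reset_index(drop=True))


def _components(binary: np.ndarray, structure: np.ndarray) -> list[np.ndarray]:
    lab, n = ndimage.label(binary, structure=structure)
    return [lab == i for i in range(1, n + 1)]


def label_clusters(
    smap: StatMap,
    threshold: float,
    connectivity: int = 26,
    two_tailed: bool = True,
    voxel_p: float | None = None,
) -> ClusterTable:
    """Connected components of the suprathreshold voxel set.

    With ``two_tailed`` both signs of exceedance are labelled, separately
    (opposite-sign voxels never merge).  Label order is deterministic:
    descending size, ties broken by descending |peak|, then lexicographic
    peak voxel index.  ``voxel_p`` is carried as metadata so the extent
    correction can verify threshold compatibility.
    """
    structure = connectivity_structure(connectivity)
    thr = abs(float(threshold))
    data = smap.data.copy()
    if smap.mask is not None:
        data = np.where(smap.mask.included, data, 0.0)
    comps: list[tuple[np.ndarray, int]] = []
    comps += [(c, +1) for c in _components(data >= thr, structure)]
    if two_tailed:
        comps += [(c, -1) for c in _components(data <= -thr, structure)]

    recs = []
    for comp, sign in comps:
        vox = np.argwhere(comp)
        vals = data[tuple(vox.T)]
        # peak = largest |stat|; ties resolved by lexicographic voxel index
        best = int(np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], -np.abs(vals)))[0])
        peak_idx = vox[best]
        peak_mm = smap.grid.affine[:3, :3] @ peak_idx + smap.grid.affine[:3, 3]
        recs.append(
            {
                "size_voxels": int(comp.sum()),
                "peak_value": float(data[tuple(peak_idx)]),
                "peak_idx": tuple(int(i) for i in peak_idx),
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "sign": sign,
                "_comp": comp,
            }
        )
    recs.sort(
        key=lambda r: (-r["size_voxels"], -abs(r["peak_value"]), r["peak_idx"])
    )

    labels = np.zeros(smap.grid.dims, dtype=int)
    rows = []
    voxvol = smap.grid.voxel_volume_mm3
    for i, rec in enumerate(recs, start=1):
        labels[rec.pop("_comp")] = i
        rec.pop("peak_idx")
        rows.append({"label": i, **rec, "size_mm3": rec["size_voxels"] * voxvol})
    cols = [
        "label",
        "size_voxels",
        "size_mm3",
        "peak_value",
        "peak_x_mm",
        "peak_y_mm",
        "peak_z_mm",
        "sign",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return ClusterTable(
        grid=smap.grid,
        labels=labels,
        df=df,
        threshold=thr,
        connectivity=int(connectivity),
        two_tailed=bool(two_tailed),
        voxel_p=voxel_p,
    )


def estimate_smoothness(maps, mask: BrainMask | None = None) -> SmoothnessEstimate:
    """Gradient-variance FWHM estimate, pooled over a list of maps.

    For each axis a with voxel size D_a, the neighbour correlation is
    rho_a = 1 - var(diff_a) / (2 var), and for a Gaussian autocorrelation
    FWHM_a = D_a * sqrt(-2 ln 2 / ln rho_a).  Non-positive rho (rougher than
    any Gaussian kernel can produce, e.g. white noise) floors the estimate
    at 0, meaning no detectable smoothness below the voxel scale.
    """
    if not isinstance(maps, (list, tuple)):
        maps = [maps]
    if len(maps) == 0:
        raise ValueError("need at least one map")
    arrays = [m.data if isinstance(m, StatMap) else np.asarray(m, float) for m in maps]
    grid = maps[0].grid if isinstance(maps[0], StatMap) else None
    voxsize = grid.voxel_size_mm if grid is not None else np.array([1.0, 1.0, 1.0])
    if mask is not None:
        voxsize = mask.grid.voxel_size_mm
        inc = mask.included
    else:
        inc = np.ones(arrays[0].shape, dtype=bool)
    if any(a.shape != inc.shape for a in arrays):
        raise ValueError("all maps must share one shape (and mask)")

    fwhm = []
    for ax in range(3):
        if inc.shape[ax] < 2:
            fwhm.append(float("nan"))
            continue
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        pair = inc[tuple(sl_a)] & inc[tuple(sl_b)]
        v_diffs, v_maps = [], []
        for a in arrays:
            vals = a[inc]
            if np.ptp(vals) == 0:
                raise ValueError("cannot estimate smoothness of a constant map")
            d = a[tuple(sl_a)] - a[tuple(sl_b)]
            v_diffs.append(d[pair].var())
            v_maps.append(vals.var())
        v_a = float(np.mean(v_diffs))
        v = float(np.mean(v_maps))
        rho = 1.0 - v_a / (2.0 * v)
        if rho <= 0:
            logger.warning(
                "axis %d neighbour correlation %.3f <= 0; flooring FWHM at 0", ax, rho
            )
            fwhm.append(0.0)
        else:
            fwhm.append(float(voxsize[ax] * np.sqrt(-2.0 * np.log(2.0) / np.log(rho))))
    return SmoothnessEstimate(tuple(fwhm))


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    lab, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def extent_threshold(
    mask: BrainMask,
    smoothness: SmoothnessEstimate,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    iterations: int = 1000,
    connectivity: int = 26,
    rng_seed: int = 0,
    two_tailed: bool = True,
) -> ExtentNull:
    """Monte-Carlo critical cluster extent at family-wise alpha.

    Each iteration draws a standard-normal field on the mask's bounding grid
    padded by 2 x FWHM, smooths it at the given per-axis FWHM, crops,
    restandardizes within the mask, thresholds at ``voxel_p`` and records
    the maximum cluster size.  The critical extent is the smallest k with
    P(max >= k) <= alpha.
    """
    if iterations < 100:
        raise ValueError("need at least 100 iterations")
    if not (0 < voxel_p < 1 and 0 < alpha <= 1):
        raise ValueError("voxel_p and alpha must lie in (0, 1)")
    if alpha < 1.0 / iterations:
        raise ValueError(
            f"alpha={alpha} is not resolvable with {iterations} iterations; "
            "increase the iteration count"
        )
    structure = connectivity_structure(connectivity)
    voxsize = mask.grid.voxel_size_mm
    fwhm = np.nan_to_num(np.asarray(smoothness.fwhm_mm, dtype=float))
    sigma_vox = fwhm * _FWHM_TO_SIGMA / voxsize
    smoothing = bool((sigma_vox > 0).any())
    pad = (
        np.ceil(2.0 * fwhm / voxsize).astype(int) if smoothing else np.zeros(3, int)
    )
    dims = np.asarray(mask.grid.dims)
    sim_dims = tuple(dims + 2 * pad)
    inc = mask.included

    if two_tailed:
        thr = stats.norm.ppf(1.0 - voxel_p / 2.0)
    else:
        thr = stats.norm.ppf(1.0 - voxel_p)

    rng = np.random.default_rng(rng_seed)
    max_sizes = np.empty(iterations, dtype=int)
    for it in range(iterations):
        f = rng.standard_normal(sim_dims)
        if smoothing:
            f = ndimage.gaussian_filter(f, sigma=sigma_vox)
            f = f[
                pad[0] : pad[0] + dims[0],
                pad[1] : pad[1] + dims[1],
                pad[2] : pad[2] + dims[2],
            ]
            # restandardize: undo the variance shrinkage of the filter
            vals = f[inc]
            f = np.where(inc, (f - vals.mean()) / vals.std(), 0.0)
        else:
            f = np.where(inc, f, 0.0)
        m = _max_cluster_size(f > thr, structure)
        if two_tailed:
            m = max(m, _max_cluster_size(f < -thr, structure))
        max_sizes[it] = m

    counts = np.bincount(max_sizes)
    tail = counts[::-1].cumsum()[::-1]  # tail[k] = #iterations with max >= k
    exceed = np.nonzero(tail / iterations <= alpha)[0]
    critical = int(exceed[0]) if exceed.size else int(len(counts))
    critical = max(critical, 1)
    return ExtentNull(
        iterations=iterations,
        voxel_p=voxel_p,
        alpha=alpha,
        connectivity=int(connectivity),
        two_tailed=two_tailed,
        max_size_counts=counts,
        critical_extent_k=critical,
        rng_seed=rng_seed,
    )


def apply_extent(table: ClusterTable, null: ExtentNull) -> ClusterTable:
    """Retain clusters >= the critical extent; annotate empirical cluster p.

    Refuses to combine a cluster table and a null built at different voxel
    thresholds or connectivities, which would silently miscalibrate.
    """
    if table.voxel_p is not None and not np.isclose(table.voxel_p, null.voxel_p):
        raise ValueError(
            f"cluster table voxel_p={table.voxel_p} does not match null "
            f"voxel_p={null.voxel_p}"
        )
    if table.connectivity != null.connectivity:
        raise ValueError(
            f"cluster table connectivity={table.connectivity} does not match "
            f"null connectivity={null.connectivity}"
        )
    df = table.df[table.df.size_voxels >= null.critical_extent_k].copy()
    df["cluster_p"] = [null.cluster_p(s) for s in df.size_voxels]
    return table.with_df(df)
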