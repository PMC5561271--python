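"""Second-level (group) statistics on Fisher-z connectivity maps.

Implements site residualization, per-group paired t maps, between-group
pooled-variance t maps, the group-by-time mixed-ANOVA interaction F map
(via the exact change-score identity for a 2-level within factor),
minimum-statistic conjunction, the restriction rule that discards
interaction clusters unsupported by a task effect in either group,
cluster-mean extraction with simple effects, and the medication post hoc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .seed import FCMap
from .volume_io import BrainMask, ImageGrid, StatMap

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectZSet",
    "residualize_site",
    "paired_t_map",
    "independent_t_map",
    "interaction_F_map",
    "interaction_t_map",
    "conjunction_mask",
    "restrict_interaction",
    "cluster_mean_z",
    "medication_posthoc",
    "oneway_f_from_samples",
]


@dataclass
class SubjectZSet:
    """Pre/post Fisher-z maps for a set of subjects, on one grid and mask.

    ``pre`` and ``post`` are (n_subjects, n_mask_voxels) arrays in the order
    of ``subjects`` rows; ``subjects`` carries subject_id, group, site and
    medicated columns.
    """

    grid: ImageGrid
    mask: BrainMask
    subjects: pd.DataFrame
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        n, v = len(self.subjects), self.mask.n_voxels
        if self.pre.shape != (n, v) or self.post.shape != (n, v):
            raise ValueError(
                f"z arrays must be ({n}, {v}); got {self.pre.shape}/{self.post.shape}"
            )
        counts = self.subjects.group.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"groups with fewer than 2 subjects: {small}")

    @classmethod
    def from_fcmaps(
        cls, records: list[tuple[dict, FCMap, FCMap]], mask: BrainMask
    ) -> "SubjectZSet":
        """records: (subject info dict, pre map, post map) triples."""
        rows, pres, posts = [], [], []
        for info, pre, post in records:
            if pre.grid != mask.grid or post.grid != mask.grid:
                raise ValueError("FCMap grid does not match mask grid")
            rows.append(info)
            pres.append(pre.z[mask.included])
            posts.append(post.z[mask.included])
        return cls(
            grid=mask.grid,
            mask=mask,
            subjects=pd.DataFrame(rows),
            pre=np.asarray(pres, dtype=float),
            post=np.asarray(posts, dtype=float),
        )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.subjects.group))

    def select(self, groups) -> "SubjectZSet":
        if isinstance(groups, str):
            groups = [groups]
        keep = self.subjects.group.isin(groups).to_numpy()
        return replace(
            self,
            subjects=self.subjects[keep].reset_index(drop=True),
            pre=self.pre[keep],
            post=self.post[keep],
        )

    def change_scores(self) -> np.ndarray:
        """Delta-z = z_post - z_pre, (n_subjects, n_mask_voxels)."""
        return self.post - self.pre

    def to_map(self, values: np.ndarray, stat_type: str = "z", df=None) -> StatMap:
        vol = np.zeros(self.grid.dims)
        vol[self.mask.included] = values
        return StatMap(self.grid, vol, stat_type=stat_type, df=df, mask=self.mask)


def residualize_site(zset: SubjectZSet) -> SubjectZSet:
    """Remove per-voxel site means, keeping the voxelwise grand intercept.

    Ordinary least squares of z on site-indicator dummies plus intercept,
    fitted jointly across all subject-sessions (both sessions of a subject
    share its site), reduces for a pure factor design to subtracting each
    site's mean and re-adding the grand mean, so maps keep their scale and
    residual site-means agree across sites at every voxel.
    """
    site = zset.subjects.site.to_numpy()
    stacked = np.concatenate([zset.pre, zset.post], axis=0)
    site2 = np.concatenate([site, site])
    grand = stacked.mean(axis=0)
    out = stacked.copy()
    for s in np.unique(site2):
        sel = site2 == s
        if sel.sum() == 1:
            logger.warning("site %s has a single subject-session; residuals are 0 there", s)
        out[sel] += grand - stacked[sel].mean(axis=0)
    n = zset.n_subjects
    return replace(zset, pre=out[:n], post=out[n:])


def _one_sample_t(d: np.ndarray) -> tuple[np.ndarray, int]:
    """Voxelwise one-sample t of rows-of-subjects array d, df = n - 1."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    if (~ok).any() and np.any(mean[~ok] != 0):
        logger.warning("zero-variance voxels with nonzero mean; t set to 0 there")
    return t, n - 1


def paired_t_map(zset: SubjectZSet) -> StatMap:
    """Two-tailed paired t (post vs pre) for a single-group z set."""
    if len(set(zset.subjects.group)) != 1:
        raise ValueError("paired_t_map expects a single-group z set")
    t, df = _one_sample_t(zset.change_scores())
    return zset.to_map(t, stat_type="t", df=df)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    t = np.zeros_like(diff)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    return t, na + nb - 2


def independent_t_map(
    zset: SubjectZSet, group_a: str, group_b: str, contrast: str = "pre"
) -> StatMap:
    """Pooled-variance two-sample t of A minus B; df = n_A + n_B - 2.

    ``contrast`` selects the per-subject scalar entering the test: "pre",
    "post", or "change" (post minus pre).
    """
    pick = {
        "pre": lambda z: z.pre,
        "post": lambda z: z.post,
        "change": lambda z: z.change_scores(),
    }
    if contrast not in pick:
        raise ValueError(f"contrast must be one of {sorted(pick)}")
    a = pick[contrast](zset.select(group_a))
    b = pick[contrast](zset.select(group_b))
    t, df = _pooled_t(a, b)
    return zset.to_map(t, stat_type="t", df=df)


def oneway_f_from_samples(samples: list[np.ndarray]) -> tuple[np.ndarray, tuple[int, int]]:
    """One-way between-group ANOVA F, voxelwise, from per-group 2D arrays."""
    k = len(samples)
    ns = np.array([s.shape[0] for s in samples])
    N = int(ns.sum())
    means = np.stack([s.mean(axis=0) for s in samples])
    grand = (ns[:, None] * means).sum(axis=0) / N
    ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    ssw = sum(((s - m) ** 2).sum(axis=0) for s, m in zip(samples, means))
    msw = ssw / (N - k)
    F = np.zeros_like(grand)
    ok = msw > 0
    F[ok] = (ssb[ok] / (k - 1)) / msw[ok]
    return F, (k - 1, N - k)


def interaction_F_map(zset: SubjectZSet, groups=None) -> StatMap:
    """Group x time interaction F of the two-way mixed ANOVA.

    For a 2-level within-subject factor the interaction F is exactly the
    one-way between-group ANOVA F on change scores d = z_post - z_pre,
    with df = (k - 1, N - k).
    """
    if groups is not None:
        zset = zset.select(groups)
    d = zset.change_scores()
    samples = [d[(zset.subjects.group == g).to_numpy()] for g in zset.groups]
    if len(samples) < 2:
        raise ValueError("interaction requires at least 2 groups")
    F, df = oneway_f_from_samples(samples)
    return zset.to_map(F, stat_type="F", df=df)


def interaction_t_map(zset: SubjectZSet, group_a: str, group_b: str) -> StatMap:
    """Signed square root of the 2-group interaction F (t on change scores)."""
    return independent_t_map(zset, group_a, group_b, contrast="change")


def conjunction_mask(
    t_a: StatMap, t_b: StatMap, threshold
) -> BrainMask:
    """Minimum-statistic conjunction: both maps beyond their threshold, same sign.

    ``threshold`` is a scalar applied to both maps, or a (thr_a, thr_b) pair
    when the maps' degrees of freedom differ.
    """
    if t_a.grid != t_b.grid:
        raise ValueError("conjunction maps live on different grids")
    thr_a, thr_b = (
        (abs(float(threshold[0])), abs(float(threshold[1])))
        if np.ndim(threshold) == 1
        else (abs(float(threshold)), abs(float(threshold)))
    )
    both_pos = (t_a.data >= thr_a) & (t_b.data >= thr_b)
    both_neg = (t_a.data <= -thr_a) & (t_b.data <= -thr_b)
    included = both_pos | both_neg
    if not included.any():
        # BrainMask forbids empty masks; return is still useful as "nothing
        # in common", so keep a raw-array escape hatch via data attribute.
        m = BrainMask.__new__(BrainMask)
        m.grid = t_a.grid
        m.included = included
        return m
    return BrainMask(t_a.grid, included)


def restrict_interaction(
    clusters,
    paired_t_maps: dict[str, StatMap],
    threshold,
) -> "ClusterTable":  # noqa: F821  (type lives in rsfc.clusters)
    """Keep interaction clusters backed by a task effect in >= 1 group.

    A cluster survives iff at least one voxel of it exceeds |t| >= threshold
    in at least one group's paired t map (threshold may be a scalar applied
    to every map, or a dict keyed like ``paired_t_maps``).  Dropped clusters
    are logged with the reason, mirroring the practice of not interpreting
    interaction clusters that show no within-group change.
    """
    kept_rows = []
    for _, row in clusters.df.iterrows():
        cluster_vox = clusters.labels == row.label
        supported = False
        for gname, tmap in paired_t_maps.items():
            thr = threshold[gname] if isinstance(threshold, dict) else threshold
            if (np.abs(tmap.data[cluster_vox]) >= abs(float(thr))).any():
                supported = True
                break
        if supported:
            kept_rows.append(row)
        else:
            logger.info(
                "dropping cluster %d (peak %.4g, %d voxels): no overlap with any "
                "group's task-effect t map",
                row.label,
                row.peak_value,
                row.size_voxels,
            )
    df = pd.DataFrame(kept_rows, columns=clusters.df.columns).reset_index(drop=True)
    return clusters.with_df(df)


@dataclass
class SimpleEffectsReport:
    """Cluster-mean z per subject-session with the standard simple effects."""

    scalars: pd.DataFrame  # subject_id, group, site, medicated, pre, post, change
    paired: pd.DataFrame  # per group: t, df, p for post vs pre
    between: pd.DataFrame  # per session and group pair: t, df, p


def cluster_mean_z(cluster: BrainMask, zset: SubjectZSet) -> SimpleEffectsReport:
    """Extract per-subject-session mean z over a cluster and test simple effects."""
    if cluster.grid != zset.grid:
        raise ValueError("cluster grid does not match z-set grid")
    sel = cluster.included[zset.mask.included]
    if not sel.any():
        raise ValueError("cluster has no voxels inside the analysis mask")
    scalars = zset.subjects.copy()
    scalars["pre"] = zset.pre[:, sel].mean(axis=1)
    scalars["post"] = zset.post[:, sel].mean(axis=1)
    scalars["change"] = scalars["post"] - scalars["pre"]

    paired_rows = []
    for g, sub in scalars.groupby("group", sort=False):
        t, p = stats.ttest_rel(sub["post"], sub["pre"])
        paired_rows.append({"group": g, "t": t, "df": len(sub) - 1, "p": p})
    paired = pd.DataFrame(paired_rows)

    between_rows = []
    groups = list(dict.fromkeys(scalars.group))
    for ses in ("pre", "post"):
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                a = scalars.loc[scalars.group == ga, ses]
                b = scalars.loc[scalars.group == gb, ses]
                t, p = stats.ttest_ind(a, b, equal_var=True)
                between_rows.append(
                    {
                        "session": ses,
                        "group_a": ga,
                        "group_b": gb,
                        "t": t,
                        "df": len(a) + len(b) - 2,
                        "p": p,
                    }
                )
    return SimpleEffectsReport(scalars, paired, pd.DataFrame(between_rows))


def medication_posthoc(zset: SubjectZSet, cluster: BrainMask) -> pd.DataFrame:
    """Time x medication mixed ANOVA on cluster-mean z within one group.

    Reuses the change-score identity with medication as the grouping factor;
    returns a one-row frame with F, df and p.
    """
    med = zset.subjects.medicated.astype(bool).to_numpy()
    if med.all() or (~med).all():
        raise ValueError("both medication levels must be present")
    if med.sum() < 2 or (~med).sum() < 2:
        raise ValueError("each medication level needs at least 2 subjects")
    sel = cluster.included[zset.mask.included]
    if not sel.any():
        raise ValueError("cluster has no voxels inside the analysis mask")
    d = (zset.post[:, sel] - zset.pre[:, sel]).mean(axis=1)
    F, (df1, df2) = oneway_f_from_samples([d[med, None], d[~med, None]])
    p = float(stats.f.sf(F[0], df1, df2))
    return pd.DataFrame(
        [{"effect": "time x medication", "F": float(F[0]), "df1": df1, "df2": df2, "p": p}]
    )
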