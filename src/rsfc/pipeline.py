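"""End-to-end analysis flows: volumes -> z maps -> corrected cluster tables.

Ties the modules together in the order a seed-based pre/post connectivity
study uses them: seed extraction and Fisher-z maps per subject-session,
site residualization, group statistics, smoothness-matched Monte-Carlo
cluster-extent correction, the interaction restriction rule, and simple
effects on surviving clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clusters import (
    ClusterTable,
    ExtentNull,
    SmoothnessEstimate,
    apply_extent,
    estimate_smoothness,
    extent_threshold,
    label_clusters,
)
from .group import (
    SimpleEffectsReport,
    SubjectZSet,
    cluster_mean_z,
    interaction_F_map,
    interaction_t_map,
    paired_t_map,
    residualize_site,
    restrict_interaction,
)
from .seed import fc_map, extract_seed_course
from .synthetic import CohortManifest, SESSIONS
from .volume_io import BrainMask, StatMap, auto_brain_mask

__all__ = [
    "compute_zset",
    "interaction_analysis",
    "task_change_analysis",
    "InteractionResult",
    "TaskChangeResult",
]


def compute_zset(
    manifest: CohortManifest,
    mask: BrainMask | str | None = None,
    confounds: np.ndarray | None = None,
    exclude_seed: bool = False,
) -> SubjectZSet:
    """Fisher-z amygdala connectivity maps for every subject in a manifest.

    ``mask`` may be a BrainMask, the string "auto" (intensity-based mask of
    the first volume), or None for all voxels.  With ``exclude_seed`` the
    seed spheres are removed from the analysis mask.
    """
    config = manifest.config
    grid = config.grid
    left, right = config.seed_spec.masks(grid)
    if mask is None:
        mask = BrainMask(grid, np.ones(grid.dims, dtype=bool))
    elif mask == "auto":
        first = manifest.subjects.iloc[0]
        mask = auto_brain_mask(manifest.load_bold(first.subject_id, SESSIONS[0]))
    if exclude_seed:
        keep = mask.included & ~(left.included | right.included)
        mask = BrainMask(grid, keep)

    records = []
    for _, sub in manifest.subjects.iterrows():
        maps = {}
        for ses in SESSIONS:
            bold = manifest.load_bold(sub.subject_id, ses)
            course = extract_seed_course(bold, left, right)
            maps[ses] = fc_map(
                bold,
                course,
                mask=mask,
                confounds=confounds,
                subject_id=sub.subject_id,
                session=ses,
            )
        records.append((sub.to_dict(), maps["pre"], maps["post"]))
    return SubjectZSet.from_fcmaps(records, mask)


@dataclass
class InteractionResult:
    """Everything the group-by-time interaction analysis produces."""

    zset: SubjectZSet  # residualized, restricted to the two groups
    f_map: StatMap
    t_change: StatMap  # signed interaction root (A minus B change scores)
    paired_t: dict[str, StatMap]
    f_threshold: float
    t_thresholds: dict[str, float]
    smoothness: SmoothnessEstimate
    null: ExtentNull
    clusters: ClusterTable  # voxel-thresholded, uncorrected
    clusters_corrected: ClusterTable
    clusters_restricted: ClusterTable
    simple_effects: dict[int, SimpleEffectsReport] = field(default_factory=dict)


def interaction_analysis(
    zset: SubjectZSet,
    group_a: str,
    group_b: str,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    iterations: int = 1000,
    connectivity: int = 26,
    rng_seed: int = 0,
    residualize: bool = True,
    restrict: bool = True,
    simple_effects: bool = True,
) -> InteractionResult:
    """Corrected, restricted group-by-time interaction analysis.

    Maps are voxel-thresholded at ``voxel_p`` (F upper tail; paired t
    two-tailed), cluster-corrected at ``alpha`` against a Monte-Carlo null
    whose smoothness is estimated from the interaction statistic map, and
    finally restricted to clusters backed by a within-group task effect.
    """
    if residualize:
        zset = residualize_site(zset)
    sel = zset.select([group_a, group_b])

    f_map = interaction_F_map(sel)
    t_change = interaction_t_map(sel, group_a, group_b)
    df1, df2 = f_map.df
    f_thr = float(stats.f.ppf(1 - voxel_p, df1, df2))

    paired = {}
    t_thresholds = {}
    for g in (group_a, group_b):
        tm = paired_t_map(sel.select(g))
        paired[g] = tm
        t_thresholds[g] = float(stats.t.ppf(1 - voxel_p / 2, tm.df))

    smoothness = estimate_smoothness([t_change], mask=sel.mask)
    clusters = label_clusters(
        f_map, f_thr, connectivity=connectivity, two_tailed=False, voxel_p=voxel_p
    )
    null = extent_threshold(
        sel.mask,
        smoothness,
        voxel_p=voxel_p,
        alpha=alpha,
        iterations=iterations,
        connectivity=connectivity,
        rng_seed=rng_seed,
        two_tailed=True,
    )
    corrected = apply_extent(clusters, null)
    restricted = (
        restrict_interaction(corrected, paired, t_thresholds) if restrict else corrected
    )

    effects: dict[int, SimpleEffectsReport] = {}
    if simple_effects:
        for label in restricted.df.label:
            effects[int(label)] = cluster_mean_z(restricted.cluster_mask(label), sel)

    return InteractionResult(
        zset=sel,
        f_map=f_map,
        t_change=t_change,
        paired_t=paired,
        f_threshold=f_thr,
        t_thresholds=t_thresholds,
        smoothness=smoothness,
        null=null,
        clusters=clusters,
        clusters_corrected=corrected,
        clusters_restricted=restricted,
        simple_effects=effects,
    )


@dataclass
class TaskChangeResult:
    t_map: StatMap
    t_threshold: float
    smoothness: SmoothnessEstimate
    null: ExtentNull
    clusters_corrected: ClusterTable


def task_change_analysis(
    zset: SubjectZSet,
    group: str,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    iterations: int = 1000,
    connectivity: int = 26,
    rng_seed: int = 0,
    residualize: bool = True,
) -> TaskChangeResult:
    """One group's corrected post-vs-pre paired t analysis (two-tailed)."""
    if residualize:
        zset = residualize_site(zset)
    sel = zset.select(group)
    t_map = paired_t_map(sel)
    thr = float(stats.t.ppf(1 - voxel_p / 2, t_map.df))
    smoothness = estimate_smoothness([t_map], mask=sel.mask)
    clusters = label_clusters(
        t_map, thr, connectivity=connectivity, two_tailed=True, voxel_p=voxel_p
    )
    null = extent_threshold(
        sel.mask,
        smoothness,
        voxel_p=voxel_p,
        alpha=alpha,
        iterations=iterations,
        connectivity=connectivity,
        rng_seed=rng_seed,
        two_tailed=True,
    )
    return TaskChangeResult(
        t_map=t_map,
        t_threshold=thr,
        smoothness=smoothness,
        null=null,
        clusters_corrected=apply_extent(clusters, null),
    )
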