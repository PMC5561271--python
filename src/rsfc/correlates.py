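"""Clinical correlates of connectivity change.

Change maps (Delta-z = z_post - z_pre), masked voxelwise Pearson correlation
of Delta-z with clinical scores (BPDSI, BSI, BPD checklist, ITEC total,
dissociation change), conversion of r maps to t maps for cluster correction,
and Bonferroni family-wise control over the correlate family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group import SubjectZSet
from .seed import FCMap
from .volume_io import BrainMask, StatMap

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalTable",
    "change_map",
    "masked_correlation_map",
    "r_to_t",
    "bonferroni_gate",
]

SCORE_COLUMNS = [
    "bpdsi",
    "bsi",
    "bpd_checklist",
    "itec_total",
    "dissociation_pre",
    "dissociation_post",
    "dissociation_change",
]


@dataclass
class ClinicalTable:
    """Per-subject clinical scores; missing values stay explicit (NaN)."""

    scores: pd.DataFrame  # indexed by subject_id

    def __post_init__(self) -> None:
        if "subject_id" in self.scores.columns:
            self.scores = self.scores.set_index("subject_id")

    @classmethod
    def from_csv(cls, path) -> "ClinicalTable":
        return cls(pd.read_csv(path))

    def aligned(self, subject_ids, score: str) -> np.ndarray:
        """Score values in the order of ``subject_ids`` (NaN where missing)."""
        if score not in self.scores.columns:
            raise KeyError(f"no clinical score named {score!r}")
        return self.scores.reindex(subject_ids)[score].to_numpy(dtype=float)


def change_map(pre: FCMap, post: FCMap) -> FCMap:
    """Delta-z map: post-task minus pre-task Fisher z, voxelwise."""
    if pre.grid != post.grid:
        raise ValueError("pre and post maps live on different grids")
    if pre.subject_id and post.subject_id and pre.subject_id != post.subject_id:
        raise ValueError(
            f"pre map belongs to {pre.subject_id!r}, post map to {post.subject_id!r}"
        )
    return FCMap(
        pre.grid,
        post.z - pre.z,
        subject_id=pre.subject_id or post.subject_id,
        session="change",
        mask=pre.mask,
    )


def masked_correlation_map(
    zset: SubjectZSet, scores: np.ndarray, mask: BrainMask
) -> StatMap:
    """Voxelwise Pearson r between per-subject Delta-z and a clinical score.

    Restricted to ``mask``; subjects with a missing score are dropped
    pairwise with the effective n logged.  df = n - 2.
    """
    if mask.grid != zset.grid:
        raise ValueError("correlation mask grid does not match z-set grid")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (zset.n_subjects,):
        raise ValueError("scores must align one-to-one with z-set subjects")
    keep = np.isfinite(scores)
    n = int(keep.sum())
    if n < 4:
        raise ValueError(f"need >= 4 subjects with scores, have {n}")
    if n < zset.n_subjects:
        logger.info("dropping %d subjects with missing scores; n = %d",
                    zset.n_subjects - n, n)
    y = scores[keep]
    if np.ptp(y) == 0:
        raise ValueError("clinical score is constant; correlation undefined")
    sel = mask.included[zset.mask.included]
    d = zset.change_scores()[keep][:, sel]  # (n, V_mask)

    y = (y - y.mean()) / np.linalg.norm(y - y.mean())
    dc = d - d.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(dc, axis=0)
    norms[norms == 0] = np.inf  # constant voxels get r = 0
    r = (dc / norms) .T @ y

    vol = np.zeros(zset.grid.dims)
    vol[mask.included] = r
    return StatMap(zset.grid, vol, stat_type="r", df=n, mask=mask)


def r_to_t(rmap: StatMap) -> StatMap:
    """t = r sqrt(n-2) / sqrt(1-r^2); lets r maps reuse t-map thresholding."""
    if rmap.stat_type != "r":
        raise ValueError("r_to_t expects an r map")
    n = int(rmap.df)
    r = np.clip(rmap.data, -1 + 1e-12, 1 - 1e-12)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    if rmap.mask is not None:
        t = np.where(rmap.mask.included, t, 0.0)
    return StatMap(rmap.grid, t, stat_type="t", df=n - 2, mask=rmap.mask)


def bonferroni_gate(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni FWE gate: reject iff p <= alpha / m over the m-test family."""
    items = (
        list(p_values.items())
        if isinstance(p_values, dict)
        else list(enumerate(np.atleast_1d(p_values)))
    )
    m = len(items)
    if m < 1:
        raise ValueError("need at least one p-value")
    adjusted = alpha / m
    rows = [
        {
            "test": name,
            "p": float(p),
            "adjusted_alpha": adjusted,
            "reject": bool(p <= adjusted),
        }
        for name, p in items
    ]
    return pd.DataFrame(rows)
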