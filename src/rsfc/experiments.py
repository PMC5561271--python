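"""Calibration and recovery experiments on synthetic cohorts.

Each function runs the real pipeline on generated data and measures one
property the method is supposed to have: Fisher-z null calibration,
family-wise error control of the Monte-Carlo cluster correction, recovery
of a planted group-by-time interaction, smoothness recovery, and recovery
of a planted clinical correlation.  They are used both by the test suite
and by the reproduction script.

Problem sizes default to scaled-down study analogues (16^3 grids, tens of
subjects) so a full calibration run stays in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage, stats

from .clusters import estimate_smoothness
from .correlates import ClinicalTable, masked_correlation_map
from .pipeline import compute_zset, interaction_analysis
from .summary import Crosstab2x2, GroupSummary, chisq_2x2, one_sample_t, oneway_anova_summary
from .synthetic import (
    ClinicalLink,
    SimConfig,
    ball_network,
    clinical_noise_sd_for_target_r,
    simulate_cohort,
)
from .volume_io import BrainMask, ImageGrid

__all__ = [
    "printed_summary_statistics",
    "fisher_null_ks",
    "null_fwe_rate",
    "interaction_recovery",
    "smoothness_recovery",
    "clinical_recovery",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _cohort_seeds(rng_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(rng_seed).integers(2**31, size=n)


def load_summary_inputs() -> dict:
    """Demographic/behavioral summary inputs shipped with the package."""
    with resources.files("rsfc").joinpath("data/table1.yaml").open() as fh:
        return yaml.safe_load(fh)


def printed_summary_statistics() -> dict[str, float]:
    """All summary statistics recomputable from the shipped summary inputs."""
    raw = load_summary_inputs()
    out: dict[str, float] = {}
    for name, d in raw["one_sample_t"].items():
        t, _ = one_sample_t(d["mean"], d["sd"], d["n"])
        out[f"t_{name}"] = t
    for name, groups in raw["anova"].items():
        F, *_ = oneway_anova_summary([GroupSummary(**g) for g in groups])
        out[f"F_{name}"] = F
    for name, tab in raw["chisq"].items():
        chi2, _ = chisq_2x2(Crosstab2x2(**tab))
        out[f"chi2_{name}"] = chi2
    return out


def fisher_null_ks(rng_seed: int = 0, dims=(22, 22, 22)) -> float:
    """KS p-value of z*sqrt(T-3) against N(0,1) on a null cohort.

    White-noise data (no coupling, no autocorrelation, no smoothing): the
    Fisher-z map of one subject-session, pooled over ~10^4 non-seed voxels,
    should be standard normal after scaling by sqrt(T-3).
    """
    config = SimConfig(
        dims=dims,
        groups=(("NPC", 2),),
        networks=(),
        clinical_links=(),
        ar1_coef=0.0,
        spatial_fwhm_mm=0.0,
        rng_seed=int(rng_seed),
    )
    manifest, _ = simulate_cohort(config)
    zset = compute_zset(manifest, exclude_seed=True)
    z = zset.pre[0]  # one subject-session, ~10^4 voxels
    scaled = z * np.sqrt(config.n_timepoints - 3)
    return float(stats.kstest(scaled, "norm").pvalue)


def _mini_config(rng_seed: int, **overrides) -> SimConfig:
    base = dict(
        dims=(16, 16, 16),
        groups=(("NPC", 10), ("BPD", 10)),
        networks=(),
        clinical_links=(),
        ar1_coef=0.0,
        rng_seed=int(rng_seed),
    )
    base.update(overrides)
    return SimConfig(**base)


def null_fwe_rate(
    n_cohorts: int = 200,
    rng_seed: int = 0,
    iterations: int = 500,
    voxel_p: float = 0.01,
    alpha: float = 0.05,
) -> dict:
    """Family-wise positive rate of the corrected interaction analysis.

    Runs the full pipeline (z maps, site residualization, interaction F,
    smoothness-matched Monte-Carlo extent correction) on null cohorts with
    no planted effects; the fraction of cohorts reporting any surviving
    cluster estimates the realized FWE, nominally ``alpha``.
    """
    seeds = _cohort_seeds(rng_seed, 2 * n_cohorts).reshape(n_cohorts, 2)
    positives = 0
    for cohort_seed, mc_seed in seeds:
        manifest, _ = simulate_cohort(_mini_config(cohort_seed))
        zset = compute_zset(manifest)
        res = interaction_analysis(
            zset,
            "NPC",
            "BPD",
            voxel_p=voxel_p,
            alpha=alpha,
            iterations=iterations,
            rng_seed=int(mc_seed),
            restrict=False,
            simple_effects=False,
        )
        if len(res.clusters_corrected) > 0:
            positives += 1
    return {"fwe_rate": positives / n_cohorts, "n_cohorts": n_cohorts}


def _planted_config(rng_seed: int, groups, coupling, n_network_voxels=40, **overrides):
    grid = ImageGrid.standard((16, 16, 16), 3.0)
    net = ball_network(grid, (0.0, 9.0, 9.0), n_network_voxels, "planted", coupling)
    return _mini_config(
        rng_seed,
        groups=groups,
        networks=(net,),
        ar1_coef=overrides.pop("ar1_coef", 0.3),
        spatial_fwhm_mm=0.0,  # keeps the atanh coupling algebra exact
        **overrides,
    )


def interaction_recovery(
    n_cohorts: int = 50,
    rng_seed: int = 0,
    iterations: int = 500,
    w_pre: float = 0.1,
    w_post: float = 0.5,
) -> dict:
    """Detection and effect-size recovery of a planted interaction.

    Group A's seed coupling in a 40-voxel network rises w_pre -> w_post
    after the task while group B stays flat; the corrected, restricted
    interaction analysis should report a surviving cluster overlapping the
    network, and group A's measured network Delta-z should recover
    atanh(w_post) - atanh(w_pre).
    """
    target = float(np.arctanh(w_post) - np.arctanh(w_pre))
    coupling = {
        ("NPC", "pre"): w_pre,
        ("NPC", "post"): w_post,
        ("BPD", "pre"): w_pre,
        ("BPD", "post"): w_pre,
    }
    seeds = _cohort_seeds(rng_seed, 2 * n_cohorts).reshape(n_cohorts, 2)
    detected = 0
    cohort_means, cohort_ses = [], []
    for cohort_seed, mc_seed in seeds:
        config = _planted_config(
            cohort_seed, (("NPC", 20), ("BPD", 20)), coupling
        )
        manifest, truth = simulate_cohort(config)
        zset = compute_zset(manifest)
        res = interaction_analysis(
            zset,
            "NPC",
            "BPD",
            iterations=iterations,
            rng_seed=int(mc_seed),
            restrict=True,
            simple_effects=False,
        )
        net = truth.network_masks["planted"]
        hit = any(
            (res.clusters_restricted.labels == lab)[net].any()
            for lab in res.clusters_restricted.df.label
        )
        detected += bool(hit)
        sel = net[zset.mask.included]
        in_a = (zset.subjects.group == "NPC").to_numpy()
        per_subject = zset.change_scores()[in_a][:, sel].mean(axis=1)
        cohort_means.append(per_subject.mean())
        cohort_ses.append(per_subject.std(ddof=1) / np.sqrt(per_subject.size))
    return {
        "detection_rate": detected / n_cohorts,
        "mean_delta_z": float(np.mean(cohort_means)),
        "se_single_cohort": float(np.mean(cohort_ses)),
        "target_delta_z": target,
        "n_cohorts": n_cohorts,
    }


def smoothness_recovery(
    rng_seed: int = 0,
    n_maps: int = 20,
    planted_fwhm_mm: float = 6.0,
    voxel_size_mm: float = 3.0,
) -> float:
    """Mean estimated FWHM (mm) of noise maps smoothed at a known kernel."""
    rng = np.random.default_rng(rng_seed)
    sigma = planted_fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    grid = ImageGrid.standard((30, 30, 30), voxel_size_mm)
    mask = BrainMask(grid, np.ones(grid.dims, dtype=bool))
    maps = []
    for _ in range(n_maps):
        f = ndimage.gaussian_filter(rng.standard_normal((40, 40, 40)), sigma)
        maps.append(f[5:-5, 5:-5, 5:-5])
    est = estimate_smoothness(maps, mask=mask)
    return est.mean_fwhm_mm


def clinical_recovery(
    n_cohorts: int = 50,
    rng_seed: int = 0,
    target_r: float = 0.45,
    n_subjects: int = 48,
) -> dict:
    """Mean recovered in-network score-vs-Delta-z correlation.

    The generator links a BPDSI-like score to each subject's true network
    Delta-z with noise tuned so the population voxel-level correlation is
    ``target_r``; the masked whole-brain correlation map should recover it
    on average over cohorts.
    """
    coupling = {("BPD", "pre"): 0.1, ("BPD", "post"): 0.5}
    seeds = _cohort_seeds(rng_seed, n_cohorts)
    mean_rs = []
    for cohort_seed in seeds:
        config = _planted_config(
            cohort_seed,
            (("BPD", n_subjects),),
            coupling,
            ar1_coef=0.0,  # keeps the Fisher-z sampling variance 2/(T-3) exact
        )
        link = ClinicalLink(
            "bpdsi",
            "planted",
            slope=20.0,
            noise_sd=clinical_noise_sd_for_target_r(
                target_r, 20.0, config.coupling_jitter_sd, config.n_timepoints
            ),
            base_mean=30.0,
        )
        config = replace(config, clinical_links=(link,))
        manifest, truth = simulate_cohort(config)
        zset = compute_zset(manifest)
        scores = ClinicalTable(manifest.clinical).aligned(
            zset.subjects.subject_id, "bpdsi"
        )
        netmask = BrainMask(config.grid, truth.network_masks["planted"])
        rmap = masked_correlation_map(zset, scores, netmask)
        mean_rs.append(rmap.data[netmask.included].mean())
    return {
        "mean_r": float(np.mean(mean_rs)),
        "target_r": target_r,
        "n_cohorts": n_cohorts,
    }
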