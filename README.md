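# rsfc

Seed-based resting-state functional-connectivity (rsFC) change analysis for
pre/post-task fMRI designs, with a synthetic multi-site cohort generator for
validation.

The package implements the analysis used to ask whether an emotion-regulation
task leaves enduring traces in amygdala connectivity, and whether those traces
differ between patient groups (borderline personality disorder, BPD;
cluster-C personality disorder, CPD) and non-patient controls (NPC):

1. **Seed connectivity.** A bilateral amygdala seed (5 mm spheres at
   Talairach ±22, −6, −14) is averaged into one time course and Pearson-
   correlated with every brain voxel; correlations are variance-stabilized
   with Fisher's transform, *z* = atanh(*r*) ≈ 𝒩(atanh(ρ), 1/(T−3)).
2. **Multi-site group inference.** Per-voxel z maps are residualized on an
   acquisition-site factor (OLS on site dummies, grand intercept retained),
   then tested with per-group paired *t* maps (post vs pre), between-group
   pooled-variance *t* maps, and the group × time interaction *F* of the
   two-way mixed ANOVA — computed exactly as the between-group ANOVA on
   change scores Δ*z* = *z*post − *z*pre, the identity that holds for a
   2-level within-subject factor.
3. **Cluster-extent FWE correction.** Maps are voxel-thresholded at
   *p* = 0.01 and corrected at cluster level *p* = 0.05 using Monte-Carlo
   simulation (default 1000 iterations) of Gaussian null fields matched to
   the statistic map's estimated smoothness (per-axis gradient-variance
   FWHM). Interaction clusters are additionally *restricted* to those
   overlapping a significant task effect in at least one group, and a
   minimum-statistic conjunction identifies networks common to both groups.
4. **Clinical correlates.** Δ*z* maps are correlated voxelwise, within a
   network mask, with clinical severity scores (BPDSI, BSI, BPD checklist,
   ITEC total, dissociation change), with Bonferroni control over the
   correlate family.
5. **Summary statistics.** One-sample *t*, one-way ANOVA from (n, mean, SD)
   summaries, and 2×2 Pearson χ² reproduce a study's demographic and
   behavioral tables exactly from printed numbers.

Because no patient imaging data are deposited, the `synthetic` module
generates cohorts with the full assumed statistical structure — AR(1) BOLD
noise, seed-coupled networks whose coupling differs by group × session,
per-site intensity offsets, spatial smoothness, and clinical scores linked
to each subject's true connectivity change — together with the ground truth
needed for recovery tests.

## Worked example

```python
import numpy as np
from rsfc import ball_network, simulate_cohort, SimConfig, ImageGrid
from rsfc.pipeline import compute_zset, interaction_analysis

# a small two-group cohort in which only NPC's network coupling rises
# from w=0.1 to w=0.5 after the task
grid = ImageGrid.standard((16, 16, 16), 3.0)
net = ball_network(grid, (0.0, 9.0, 9.0), 40, "mpfc", {
    ("NPC", "pre"): 0.1, ("NPC", "post"): 0.5,
    ("BPD", "pre"): 0.1, ("BPD", "post"): 0.1,
})
config = SimConfig(dims=(16, 16, 16), groups=(("NPC", 20), ("BPD", 20)),
                   networks=(net,), clinical_links=(), spatial_fwhm_mm=0.0,
                   ar1_coef=0.0, rng_seed=7)
manifest, truth = simulate_cohort(config)

zset = compute_zset(manifest)
res = interaction_analysis(zset, "NPC", "BPD", iterations=500, rng_seed=1)
top = res.clusters_restricted.df.iloc[0]
print(f"critical extent k = {res.null.critical_extent_k} voxels")
print(f"top cluster: {top.size_voxels} voxels ({top.size_mm3:.0f} mm^3), "
      f"peak F = {top.peak_value:.1f} at "
      f"({top.peak_x_mm:.0f}, {top.peak_y_mm:.0f}, {top.peak_z_mm:.0f}) mm")
rep = res.simple_effects[int(top.label)]
print(rep.paired.round(4).to_string(index=False))
```

prints

```
critical extent k = 4 voxels
top cluster: 42.0 voxels (1134 mm^3), peak F = 61.0 at (-4, 4, 8) mm
group      t  df      p
  NPC 9.2023  19 0.0000
  BPD 0.6291  19 0.5368
```

The corrected, restricted interaction analysis recovers the planted 40-voxel
network (42 suprathreshold voxels — the 40 planted plus two noise neighbours),
and the simple effects localize the post-task connectivity increase to the
NPC group, whose true cluster-mean change is atanh(0.5) − atanh(0.1) = 0.449.

A CLI mirrors the pipeline (`rsfc simulate | fc | stats | cluster |
correlate | table1`); see `rsfc --help`.

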