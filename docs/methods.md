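# Methods

This note documents the statistical model behind the package, the choices
made where the method is genuinely under-determined, and what the synthetic
validation does and does not establish.

## Connectivity model

For each subject and session a bilateral seed (two 5 mm spheres, default
centres ±22, −6, −14 mm) is reduced to one time course — the mean of the
left-sphere mean and the right-sphere mean — and correlated with every
voxel's time course over all T timepoints (default T = 180, TR = 2 s).
Pearson r is mapped to Fisher z = atanh(r); |r| is clipped at 1 − 10⁻⁷ so
self-correlated voxels stay finite, and zero-variance voxels get z = 0 with
a logged warning. Seed voxels are *included* in the map: the resulting
self-correlation ring is innocuous for group contrasts (it is common to
both sessions and groups) and keeps the self-correlation contract testable.
An optional confound matrix is residualized out of seed and voxel courses
first; by default none is used, since the synthetic data contain no
nuisance processes.

For white series, z is approximately Normal(atanh(ρ), 1/(T−3)); with AR(1)
autocorrelation the variance is inflated by roughly (1+φ²)/(1−φ²), which is
why the calibration experiments that assert the exact 1/(T−3) scaling
generate white noise (φ = 0).

## Site handling

Multi-site acquisition enters as a per-voxel additive site effect. Ordinary
least squares of z on site-indicator dummies (fitted jointly across all
subject-sessions; both sessions of a subject share its site) reduces to
subtracting each site's mean and re-adding the grand mean, so maps keep an
interpretable scale and per-site means agree exactly afterwards. Because
the same site mean is removed from both sessions, change scores are
invariant to the operation — site correction matters for baseline and
per-session contrasts, not for within-subject change.

## Group inference

* Per-group task effect: two-tailed paired t on z_post − z_pre, df = n − 1.
* Baseline group difference: pooled-variance two-sample t, df = n_A+n_B−2
  (pooled, not Welch, to stay inside the classical ANOVA framework).
* Group × time interaction: for a 2-level within factor the mixed-ANOVA
  interaction F equals the one-way between-group ANOVA F on change scores,
  df = (k−1, N−k). This identity is exact (verified in tests against a
  brute-force OLS model-comparison mixed ANOVA and against pingouin), so
  the change-score route is the implementation.
* Conjunction: minimum-statistic rule — a voxel is "common" iff both maps
  exceed their own two-tailed threshold in the same direction.
* Restriction: corrected interaction clusters are kept only if at least one
  voxel overlaps a suprathreshold voxel (same voxel p, two-tailed) of at
  least one group's paired t map. The overlap rule is ≥ 1 voxel.
* Medication post hoc: the same interaction machinery applied to
  cluster-mean z with medication as the grouping factor.

Voxel thresholds: two-tailed p for t maps (|t| ≥ t_{1−p/2,df}), upper-tail
p for F maps. The default voxel p is 0.01 and cluster alpha 0.05.

## Cluster-extent correction

Suprathreshold voxels are labelled by 26-connectivity by default (6 and 18
available); positive and negative exceedances are never merged. Label order
is deterministic: descending size, ties by |peak|, then lexicographic peak
index. Cluster sizes are reported in native voxels and mm³ (multiples of
the 27 mm³ voxel volume; correction tools that interpolate statistics to a
finer grid can print extents that are not such multiples — this package
does not emulate interpolation).

The critical extent is Monte-Carlo: each iteration draws a standard-normal
field on the mask's bounding box (padded by 2×FWHM when smoothing),
Gaussian-smooths it to the target FWHM, crops, restandardizes within the
mask (only when smoothing was applied — restandardizing an unsmoothed
standard-normal draw would distort small masks), thresholds two-tailed at
the voxel p, and records the maximum cluster size. The critical extent k is
the smallest size with P(max ≥ k) ≤ alpha, and surviving clusters carry
their empirical cluster-level p. Null and data tables must agree on voxel p
and connectivity or the combination is refused.

### Smoothness

Per-axis FWHM comes from the gradient-variance estimator: with neighbour
correlation rho_a = 1 − var(diff_a)/(2 var), a Gaussian autocorrelation
gives FWHM_a = Δ_a sqrt(−2 ln 2 / ln rho_a). Non-positive rho floors the
estimate at 0 ("no smoothness detectable below the voxel scale") — the
estimator's true white-noise limit. Flooring at the voxel size instead
would make the null fields smoother than genuinely unsmooth data and was
measured to push the realized family-wise error far below nominal.

The pipeline estimates smoothness **from the statistic map itself** (the
signed interaction-t map, or the paired t map) rather than from
second-level residual maps. Low-df t fields are rougher than their
residual fields — the spatially varying denominator multiplies in extra
roughness — and Gaussian nulls matched to residual smoothness were
measured to be strongly conservative (realized FWE near 0 at nominal
0.05), while statistic-map smoothness yields a realized FWE of ~0.04–0.06
on 200 null cohorts. The residual route remains available by passing any
list of maps to `estimate_smoothness`.

## Synthetic cohorts

Per subject-session the generator draws a latent seed signal s(t) and
i.i.d. noise fields ε, both stationary unit-variance AR(1):

* seed voxels: s + seed_noise_sd·ε (default 0.3 — the seed carries its
  signal with modest voxel noise, and the 38-voxel average tracks s at
  r > 0.99);
* voxels of a named network with coupling w: w·s + sqrt(1−w²)·ε, so the
  population voxel-seed correlation is w and the marginal variance is
  noise_sd² regardless of w;
* background voxels: ε.

Volumes are scaled by noise_sd, optionally Gaussian-smoothed in space, and
offset by per-site baseline gain/offset. Defaults are chosen once as the
realistic study condition: 180 timepoints at TR 2 s, 3 mm voxels, 3 sites,
groups of 48/39/21, AR(1) coefficient 0.3 (BOLD-like temporal
autocorrelation), spatial FWHM 6 mm (preprocessed EPI is spatially smooth),
site offset SD 5 intensity units on a baseline of 100.

Coupling weights are jittered per subject-session on the atanh scale
(SD 0.15, applied only where w > 0 so null cohorts stay null). The jitter
serves two purposes: it gives each subject a well-defined *true* Fisher-z
change, and it makes a population clinical correlation definable. A linked
clinical score is base_mean + slope·(true Δz) + Gaussian noise; the helper
`clinical_noise_sd_for_target_r` solves the attenuation identity

    r = slope·var_t / ( sqrt(slope²·var_t + var_noise) · sqrt(var_t + 2/(T−3)) ),

with var_t = 2·jitter², for the noise SD that realizes a target population
correlation against a single voxel's measured Δz. Unlinked scores (BSI,
checklist, ITEC subscales, dissociation) are drawn from group-wise
means/SDs of the study population and clipped at 0. Medication is assigned
at random within the BPD group at the study proportion (31/48).

Everything is bitwise-reproducible from (config, rng_seed); volumes are
generated lazily from per-session RNG keys, or materialized to NIfTI with
a manifest CSV, clinical CSV and ground-truth JSON.

## Validation experiments and problem sizes

The experiments (in `rsfc.experiments`, shared by the test suite and the
reproduction script) run the real pipeline on generated cohorts:

* **Fisher-z null calibration** — one null subject-session on a 22³ grid
  (~10⁴ non-seed voxels), white noise: KS test of z·sqrt(T−3) against
  N(0,1).
* **FWE calibration** — 200 null mini-cohorts (16³ grid, 2 groups × 10
  subjects, 3 sites, AR(1) = 0 with the default 6 mm smoothing, 500
  Monte-Carlo iterations each): fraction of cohorts with any surviving
  corrected interaction cluster, nominally 0.05, accepted in the binomial
  band [0.02, 0.09].
* **Interaction recovery** — 50 cohorts with a 40-voxel network coupled
  0.1 → 0.5 after the task in one group only (n = 20/20): detection rate of
  a surviving restricted cluster overlapping the true network, and recovery
  of Δz = atanh(0.5) − atanh(0.1) = 0.449 within 2 SE of a single cohort's
  estimate. These cohorts use spatial FWHM 0 because the atanh coupling
  algebra is exact only without spatial mixing of network and background.
* **Smoothness recovery** — 20 noise maps smoothed at 6 mm on a 3 mm grid:
  mean estimate within [5, 7] mm.
* **Clinical recovery** — 50 single-group cohorts (n = 48) with the score
  noise tuned for population r = 0.45: mean in-network voxelwise r within
  [0.35, 0.55].

What passing these shows: the implementation is internally calibrated and
recovers what the generator plants at realistic sizes. What it does not
show: robustness to real-data features the generator omits — motion and
physiological artifacts, non-Gaussian spatial autocorrelation (real EPI
smoothness has heavier-than-Gaussian tails, a known source of cluster-level
anticonservatism), field inhomogeneity near the amygdala, hemodynamic
convolution, and site differences beyond additive intensity effects.

## Numerical details and edge cases

* mm→voxel mapping rounds half away from zero per axis, deterministically;
  out-of-bounds coordinates raise with the offending coordinate.
* Empty seed spheres (radius below the nearest voxel-centre distance)
  raise and suggest the nearest-voxel fallback.
* Zero-variance differences give t = 0 (never ±inf) with a warning; a
  constant score or constant map is refused rather than silently NaN.
* Bonferroni family for cluster correlates: m = clusters × scales by
  default; the family definition is reported alongside the decisions.
* The substance-abuse χ² of the printed counts evaluates to 10.2247
  (printed: 10.23); counts are treated as authoritative and comparisons are
  made at the printed 2-decimal precision (±0.01). All other printed
  statistics reproduce exactly at 2 decimals.

## Known limitations

* No spatial normalization, motion correction or nuisance regression —
  inputs are assumed preprocessed and in a common stereotaxic frame.
* The Gaussian-field Monte-Carlo null with a single pooled FWHM is the
  classical correction, not a permutation test; its accuracy degrades for
  very low df and non-Gaussian smoothness.
* Education-level and multivariate trauma analyses from the demographic
  table are out of scope (insufficient printed detail).
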