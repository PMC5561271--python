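"""Second-level statistics: residualization, t/F maps, conjunction, restriction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsfc import (
    BrainMask,
    ImageGrid,
    StatMap,
    cluster_mean_z,
    conjunction_mask,
    independent_t_map,
    interaction_F_map,
    interaction_t_map,
    label_clusters,
    medication_posthoc,
    paired_t_map,
    residualize_site,
    restrict_interaction,
)
from rsfc.summary import one_sample_t

from conftest import make_zset


def mixed_anova_interaction_oracle(d_pre, d_post, groups):
    """Brute-force two-way mixed ANOVA interaction F by OLS model comparison.

    Long-format model with subject dummies (absorbing all between-subject
    structure), a time main effect, and group-by-time terms; the interaction
    F compares residual sums of squares with and without those terms.
    """
    n = len(groups)
    y = np.concatenate([d_pre, d_post])
    subj = np.tile(np.eye(n), (2, 1))
    time = np.concatenate([np.zeros(n), np.ones(n)])[:, None]
    labels = sorted(set(groups))
    glabels = np.tile(np.asarray(groups), 2)
    gt = np.column_stack([time[:, 0] * (glabels == g) for g in labels[1:]])
    X_red = np.column_stack([subj, time])
    X_full = np.column_stack([X_red, gt])
    ssr = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
    k = len(labels)
    df1, df2 = k - 1, n - k
    F = ((ssr(X_red) - ssr(X_full)) / df1) / (ssr(X_full) / df2)
    return F, (df1, df2)


class TestResidualizeSite:
    def test_single_site_is_identity(self, grid8, zset_factory):
        zset = zset_factory(grid8, (4, 4), sites=1)
        out = residualize_site(zset)
        np.testing.assert_allclose(out.pre, zset.pre, atol=1e-12)
        np.testing.assert_allclose(out.post, zset.post, atol=1e-12)

    def test_two_sites_exact_fit(self, grid8):
        zset = make_zset(grid8, (2, 2), n_voxels=1, sites=2)
        zset.pre[:] = [[1.0], [3.0], [1.0], [3.0]]
        zset.post[:] = zset.pre
        zset.subjects["site"] = [0, 1, 0, 1]
        out = residualize_site(zset)
        np.testing.assert_allclose(out.pre, 2.0)  # residual 0 + intercept 2
        np.testing.assert_allclose(out.post, 2.0)

    def test_site_means_are_annihilated(self, grid8, rng):
        zset = make_zset(grid8, (6, 6), rng=rng)
        offsets = {0: 1.5, 1: -0.7, 2: 0.3}
        for i, site in enumerate(zset.subjects.site):
            zset.pre[i] += offsets[site]
            zset.post[i] += offsets[site]
        out = residualize_site(zset)
        stacked = np.concatenate([out.pre, out.post])
        site2 = np.concatenate([out.subjects.site] * 2)
        means = [stacked[site2 == s].mean(axis=0) for s in (0, 1, 2)]
        np.testing.assert_allclose(means[0], means[1], atol=1e-10)
        np.testing.assert_allclose(means[0], means[2], atol=1e-10)

    def test_group_statistics_invariant_to_site_constants(self, grid8, rng):
        zset = make_zset(grid8, (5, 5), rng=rng)
        f_clean = interaction_F_map(residualize_site(zset)).data
        shifted = make_zset(grid8, (5, 5), rng=np.random.default_rng(1234))
        shifted.pre = zset.pre.copy()
        shifted.post = zset.post.copy()
        shifted.subjects = zset.subjects.copy()
        for i, site in enumerate(shifted.subjects.site):
            shifted.pre[i] += 10.0 * site
            shifted.post[i] += 10.0 * site
        f_shifted = interaction_F_map(residualize_site(shifted)).data
        np.testing.assert_allclose(f_clean, f_shifted, atol=1e-8)


class TestTMaps:
    def test_paired_t_hand_example(self, grid8):
        zset = make_zset(grid8, (3,), n_voxels=1, groups=("A",))
        zset.pre[:] = 0.0
        zset.post[:] = [[1.0], [2.0], [3.0]]
        tmap = paired_t_map(zset)
        assert tmap.data.ravel()[0] == pytest.approx(2 * np.sqrt(3))
        assert tmap.df == 2

    def test_paired_t_null_and_summary_equivalence(self, grid8, rng):
        zset = make_zset(grid8, (8,), groups=("A",), rng=rng)
        d = zset.change_scores()
        tmap = paired_t_map(zset)
        v = 17
        t_ref, df_ref = one_sample_t(d[:, v].mean(), d[:, v].std(ddof=1), 8)
        flat = tmap.data[zset.mask.included]
        assert flat[v] == pytest.approx(t_ref, rel=1e-12)
        assert tmap.df == df_ref

    def test_paired_t_zero_variance_yields_zero(self, grid8):
        zset = make_zset(grid8, (3,), n_voxels=1, groups=("A",))
        zset.pre[:] = 1.0
        zset.post[:] = 1.0
        assert paired_t_map(zset).data.ravel()[0] == 0.0

    def test_independent_t_hand_example(self, grid8):
        zset = make_zset(grid8, (2, 2), n_voxels=1)
        zset.pre[:] = [[0.0], [1.0], [2.0], [3.0]]
        tmap = independent_t_map(zset, "A", "B", contrast="pre")
        assert tmap.data.ravel()[0] == pytest.approx(-2.828, abs=1e-3)
        assert tmap.df == 2

    def test_baseline_df_bookkeeping_for_study_sizes(self, grid8):
        zset = make_zset(grid8, (48, 39), n_voxels=2, groups=("BPD", "NPC"))
        tmap = independent_t_map(zset, "BPD", "NPC", contrast="pre")
        assert tmap.df == 85  # printed baseline contrast df


class TestInteractionF:
    def test_identical_groups_give_zero(self, grid8):
        zset = make_zset(grid8, (3, 3), n_voxels=1)
        zset.pre[:] = 0.0
        zset.post[:] = [[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]]
        assert interaction_F_map(zset).data.ravel()[0] == pytest.approx(0.0)

    def test_f_equals_squared_t_on_change_scores(self, grid8, rng):
        zset = make_zset(grid8, (6, 5), rng=rng)
        F = interaction_F_map(zset).data
        t = interaction_t_map(zset, "A", "B").data
        np.testing.assert_allclose(F, t**2, rtol=1e-10)

    def test_df_bookkeeping_for_study_sizes(self, grid8):
        zset = make_zset(grid8, (48, 39), n_voxels=2, groups=("BPD", "NPC"))
        assert interaction_F_map(zset).df == (1, 85)

    @pytest.mark.parametrize("sizes,groups", [((4, 5), "AB"), ((4, 3, 5), "ABC")])
    def test_agrees_with_brute_force_mixed_anova(self, grid8, rng, sizes, groups):
        zset = make_zset(grid8, sizes, n_voxels=20, rng=rng, groups=tuple(groups))
        F = interaction_F_map(zset).data[zset.mask.included]
        labels = zset.subjects.group.tolist()
        for v in range(20):
            F_ref, df_ref = mixed_anova_interaction_oracle(
                zset.pre[:, v], zset.post[:, v], labels
            )
            assert F[v] == pytest.approx(F_ref, rel=1e-10)
        assert interaction_F_map(zset).df == df_ref

    def test_agrees_with_pingouin_mixed_anova(self, grid8, rng):
        pg = pytest.importorskip("pingouin")
        zset = make_zset(grid8, (6, 6), n_voxels=3, rng=rng)
        F = interaction_F_map(zset).data[zset.mask.included]
        v = 1
        long = pd.DataFrame(
            {
                "y": np.concatenate([zset.pre[:, v], zset.post[:, v]]),
                "time": ["pre"] * 12 + ["post"] * 12,
                "subject": list(zset.subjects.subject_id) * 2,
                "group": list(zset.subjects.group) * 2,
            }
        )
        aov = pg.mixed_anova(long, dv="y", within="time", subject="subject",
                             between="group")
        F_ref = float(aov.loc[aov.Source == "Interaction", "F"].iloc[0])
        assert F[v] == pytest.approx(F_ref, rel=1e-8)

    def test_single_group_rejected(self, grid8):
        zset = make_zset(grid8, (4,), groups=("A",))
        with pytest.raises(ValueError):
            interaction_F_map(zset)


class TestConjunction:
    def _map(self, grid, values, df=10):
        return StatMap(grid, values, stat_type="t", df=df)

    def test_identical_maps_reduce_to_own_threshold(self, grid8, rng):
        vals = rng.standard_normal(grid8.dims) * 3
        m = self._map(grid8, vals)
        conj = conjunction_mask(m, m, 2.66)
        np.testing.assert_array_equal(conj.included, np.abs(vals) >= 2.66)

    def test_opposite_signs_are_excluded(self, grid8):
        a = np.zeros(grid8.dims)
        b = np.zeros(grid8.dims)
        a[2, 2, 2], b[2, 2, 2] = 4.0, -4.0
        conj = conjunction_mask(self._map(grid8, a), self._map(grid8, b), 2.66)
        assert not conj.included.any()

    def test_per_map_thresholds(self, grid8):
        a = np.zeros(grid8.dims)
        b = np.zeros(grid8.dims)
        a[1, 1, 1], b[1, 1, 1] = 3.0, 2.8
        conj = conjunction_mask(self._map(grid8, a), self._map(grid8, b), (2.9, 2.7))
        assert conj.included[1, 1, 1]
        conj2 = conjunction_mask(self._map(grid8, a), self._map(grid8, b), (2.9, 2.9))
        assert not conj2.included.any()


class TestRestriction:
    def test_eight_planted_clusters_six_survive(self):
        """Mirrors dropping interaction clusters unsupported by any group's
        task effect: 8 corrected clusters, 2 without support -> 6 kept."""
        grid = ImageGrid.standard((12, 12, 12), 3.0)
        f = np.zeros(grid.dims)
        centers = [(1, 1, 1), (1, 1, 9), (1, 9, 1), (9, 1, 1),
                   (9, 9, 1), (9, 1, 9), (1, 9, 9), (9, 9, 9)]
        for c in centers:
            f[c] = f[c[0] + 1, c[1], c[2]] = 10.0
        fmap = StatMap(grid, f, stat_type="F", df=(1, 18))
        table = label_clusters(fmap, 7.0, two_tailed=False, voxel_p=0.01)
        assert len(table) == 8
        t_a = np.zeros(grid.dims)
        t_b = np.zeros(grid.dims)
        for c in centers[:4]:
            t_a[c] = 4.0  # supported by group A's task effect
        for c in centers[4:6]:
            t_b[c] = -4.0  # supported by group B (negative direction counts)
        maps = {
            "A": StatMap(grid, t_a, stat_type="t", df=19),
            "B": StatMap(grid, t_b, stat_type="t", df=19),
        }
        kept = restrict_interaction(table, maps, 2.86)
        assert len(kept) == 6
        dropped_sizes = set(table.df.label) - set(kept.df.label)
        assert len(dropped_sizes) == 2

    def test_fully_supported_cluster_kept(self, grid8):
        f = np.zeros(grid8.dims)
        f[3, 3, 3] = 9.0
        table = label_clusters(
            StatMap(grid8, f, stat_type="F", df=(1, 10)), 7.0, two_tailed=False
        )
        t = np.zeros(grid8.dims)
        t[3, 3, 3] = 5.0
        kept = restrict_interaction(
            table, {"A": StatMap(grid8, t, stat_type="t", df=11)}, 3.0
        )
        assert len(kept) == 1


class TestClusterMeanZ:
    def test_single_voxel_cluster_returns_that_voxel(self, grid8, rng):
        zset = make_zset(grid8, (3, 3), rng=rng)
        inc = np.zeros(grid8.dims, dtype=bool)
        inc[0, 0, 0] = True
        rep = cluster_mean_z(BrainMask(grid8, inc), zset)
        np.testing.assert_allclose(rep.scalars["pre"], zset.pre[:, 0])

    def test_homogeneous_cluster_value(self, grid8):
        zset = make_zset(grid8, (3, 3))
        zset.pre[:] = 0.7
        zset.post[:] = 0.7
        inc = np.zeros(grid8.dims, dtype=bool)
        inc[1:3, 1:3, 1:3] = True
        rep = cluster_mean_z(BrainMask(grid8, inc), zset)
        np.testing.assert_allclose(rep.scalars["pre"], 0.7)
        np.testing.assert_allclose(rep.scalars["change"], 0.0)

    def test_simple_effects_localize_the_affected_group(self, grid8):
        """A planted change in group A only shows up as a significant paired
        effect in A and not in B, with a significant post-session group gap."""
        rng = np.random.default_rng(5)
        zset = make_zset(grid8, (20, 20), rng=rng, effect={"A": 0.45})
        inc = np.ones(grid8.dims, dtype=bool)
        rep = cluster_mean_z(BrainMask(grid8, inc), zset)
        p_a = rep.paired.loc[rep.paired.group == "A", "p"].iloc[0]
        p_b = rep.paired.loc[rep.paired.group == "B", "p"].iloc[0]
        assert p_a < 0.05 < p_b
        post = rep.between[rep.between.session == "post"]
        assert post["p"].iloc[0] < 0.05


class TestMedicationPosthoc:
    def test_degenerate_factor_rejected(self, grid8):
        zset = make_zset(grid8, (6,), groups=("BPD",))
        zset.subjects["medicated"] = True
        inc = np.ones(grid8.dims, dtype=bool)
        with pytest.raises(ValueError, match="medication"):
            medication_posthoc(zset, BrainMask(grid8, inc))

    def test_f_equals_squared_t_on_cluster_scalars(self, grid8, rng):
        zset = make_zset(grid8, (12,), groups=("BPD",), rng=rng)
        inc = np.ones(grid8.dims, dtype=bool)
        rep = medication_posthoc(zset, BrainMask(grid8, inc))
        med = zset.subjects.medicated.to_numpy(bool)
        d = zset.change_scores().mean(axis=1)
        t, p = stats.ttest_ind(d[med], d[~med], equal_var=True)
        assert rep.F.iloc[0] == pytest.approx(t**2, rel=1e-10)

    def test_null_permutation_calibration(self, grid8):
        """Permuting medication labels on null data rejects at ~alpha."""
        rng = np.random.default_rng(9)
        zset = make_zset(grid8, (16,), groups=("BPD",), rng=rng)
        inc = np.ones(grid8.dims, dtype=bool)
        mask = BrainMask(grid8, inc)
        rejections = 0
        n_perm = 200
        for _ in range(n_perm):
            zset.subjects["medicated"] = rng.permutation(
                [True] * 8 + [False] * 8
            )
            p = medication_posthoc(zset, mask).p.iloc[0]
            rejections += p < 0.05
        assert 0.01 <= rejections / n_perm <= 0.11
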