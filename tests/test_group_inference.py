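"""Group-level statistics against brute-force scalar oracles."""

import numpy as np
import pytest
from scipy import ndimage, stats

from qmtpipe.group_inference import (
    StatMap,
    exclusive_mask,
    extract_clusters,
    grand_mean_scale,
    monte_carlo_cluster_threshold,
    paired_t_map,
    regress_change_on_covariate,
    repeated_measures_interaction,
    roi_fwe_smallvolume,
    roi_mean_change,
    smooth_volume,
)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((8, 8, 4))
        assert np.array_equal(smooth_volume(vol, 0.0, 3.0), vol)

    def test_constant_map_preserved_under_mask(self):
        mask = np.zeros((12, 12, 6), bool)
        mask[2:10, 2:10, 1:5] = True
        vol = np.where(mask, 7.5, np.nan)
        sm = smooth_volume(vol, 8.0, 3.0, mask=mask)
        np.testing.assert_allclose(sm[mask], 7.5, rtol=1e-10)
        assert np.isnan(sm[~mask]).all()

    def test_delta_spike_profile_has_requested_fwhm(self):
        fwhm, voxel = 8.0, 1.0
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        sm = smooth_volume(vol, fwhm, voxel)
        profile = sm[:, 20, 20]
        half = profile.max() / 2.0
        above = np.nonzero(profile >= half)[0]
        # sub-voxel interpolation of the half-max crossings
        lo, hi = above[0], above[-1]
        frac_lo = (profile[lo] - half) / (profile[lo] - profile[lo - 1])
        frac_hi = (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        width = (hi + frac_hi) - (lo - frac_lo)
        assert width * voxel == pytest.approx(fwhm, rel=0.05)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((4, 4, 4)), -1.0, 3.0)


class TestPairedT:
    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((6, 5, 5, 3))
        mask = np.ones((5, 5, 3), bool)
        stat = paired_t_map(a, a.copy(), mask)
        assert stat.mask.all()
        assert np.all(stat.t == 0.0)

    def test_constant_nonzero_difference_flagged_invalid(self):
        a = np.ones((5, 4, 4, 2))
        b = np.zeros((5, 4, 4, 2))
        stat = paired_t_map(a, b, np.ones((4, 4, 2), bool))
        assert not stat.mask.any()
        assert np.isnan(stat.t).all()

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((9, 4, 3, 2))
        b = rng.standard_normal((9, 4, 3, 2))
        mask = np.ones((4, 3, 2), bool)
        stat = paired_t_map(a, b, mask)
        assert stat.df == 8
        for idx in np.ndindex(4, 3, 2):
            d = a[(slice(None),) + idx] - b[(slice(None),) + idx]
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert stat.t[idx] == pytest.approx(t_ref, abs=1e-12)

    def test_mismatched_counts_raise(self):
        with pytest.raises(ValueError):
            paired_t_map(
                np.zeros((4, 2, 2, 2)), np.zeros((5, 2, 2, 2)),
                np.ones((2, 2, 2), bool),
            )


def _flood_fill_labels(supra, neighbors):
    """Independent BFS connected-components oracle."""
    labels = np.zeros(supra.shape, int)
    current = 0
    for start in np.argwhere(supra):
        start = tuple(start)
        if labels[start]:
            continue
        current += 1
        queue = [start]
        labels[start] = current
        while queue:
            vox = queue.pop()
            for off in neighbors:
                nb = tuple(np.array(vox) + off)
                if any(c < 0 or c >= s for c, s in zip(nb, supra.shape)):
                    continue
                if supra[nb] and not labels[nb]:
                    labels[nb] = current
                    queue.append(nb)
    return labels


class TestClusters:
    def _statmap(self, t):
        return StatMap(t=t, df=19, n_pairs=20, mask=np.isfinite(t))

    def test_single_suprathreshold_voxel(self):
        t = np.zeros((6, 6, 4))
        t[3, 3, 2] = 10.0
        clusters = extract_clusters(self._statmap(t), 0.001)
        assert len(clusters) == 1
        assert clusters[0].extent == 1
        assert clusters[0].peak_index == (3, 3, 2)

    def test_diagonal_connectivity_semantics(self):
        t = np.zeros((6, 6, 4))
        t[2, 2, 1] = t[3, 3, 2] = 8.0  # touch only at a corner
        c26 = extract_clusters(self._statmap(t), 0.001, connectivity=26)
        c6 = extract_clusters(self._statmap(t), 0.001, connectivity=6)
        assert len(c26) == 1 and c26[0].extent == 2
        assert len(c6) == 2

    @pytest.mark.parametrize("connectivity,n_nb", [(6, 6), (26, 26)])
    def test_labels_match_flood_fill_oracle(self, connectivity, n_nb):
        rng = np.random.default_rng(3)
        t = rng.standard_normal((10, 9, 6)) * 3
        stat = self._statmap(t)
        clusters = extract_clusters(stat, 0.01, connectivity=connectivity)
        t_crit = stats.t.isf(0.01, stat.df)
        supra = t > t_crit
        if connectivity == 6:
            neighbors = [o for o in np.ndindex(3, 3, 3)
                         if sum(abs(np.array(o) - 1)) == 1]
        else:
            neighbors = [o for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)]
        neighbors = [np.array(o) - 1 for o in neighbors]
        oracle = _flood_fill_labels(supra, neighbors)
        assert oracle.max() == len(clusters)
        sizes = sorted(np.bincount(oracle.ravel())[1:], reverse=True)
        assert sizes == [c.extent for c in clusters]

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            extract_clusters(self._statmap(np.zeros((4, 4, 4))), 0.01,
                             connectivity=8)


class TestMonteCarloExtent:
    def test_unsmoothed_tiny_p_gives_extent_one(self):
        mask = np.ones((10, 10, 10), bool)
        mc = monte_carlo_cluster_threshold(
            mask, 0.0, 3.0, p_voxel=1e-6, n_iter=200, alpha=0.05, seed=1
        )
        # expected suprathreshold count 1e-3 per iteration: max extents ~ 0
        assert mc.k_star == 1
        assert (mc.max_extents == 0).mean() > 0.99

    def test_deterministic_given_seed(self):
        mask = np.ones((8, 8, 4), bool)
        a = monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=150, seed=7)
        b = monte_carlo_cluster_threshold(mask, 6.0, 3.0, n_iter=150, seed=7)
        assert a.k_star == b.k_star
        assert np.array_equal(a.max_extents, b.max_extents)

    def test_smoothing_enlarges_null_clusters(self):
        mask = np.ones((16, 16, 8), bool)
        raw = monte_carlo_cluster_threshold(mask, 0.0, 3.0, n_iter=150, seed=2)
        sm = monte_carlo_cluster_threshold(mask, 8.0, 3.0, n_iter=150, seed=2)
        assert sm.k_star > raw.k_star

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_cluster_threshold(np.zeros((4, 4, 4), bool), 8.0, 3.0)


class TestRoiFwe:
    def test_full_enumeration_p_granularity(self):
        rng = np.random.default_rng(4)
        maps_a = rng.standard_normal((5, 4, 4, 2))
        maps_b = rng.standard_normal((5, 4, 4, 2))
        roi = np.zeros((4, 4, 2), bool)
        roi[1:3, 1:3, :] = True
        _, _, p = roi_fwe_smallvolume(maps_a, maps_b, roi, n_perm=64)
        assert (p * 32) == pytest.approx(round(p * 32), abs=1e-9)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(5)
        roi = np.ones((3, 3, 2), bool)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            a = rng.standard_normal((8, 3, 3, 2))
            b = rng.standard_normal((8, 3, 3, 2))
            _, _, p = roi_fwe_smallvolume(a, b, roi, n_perm=256)
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(6)
        roi = np.ones((3, 3, 2), bool)
        hits = 0
        for _ in range(40):
            a = rng.standard_normal((10, 3, 3, 2)) + 3.0  # 3x noise SD shift
            b = rng.standard_normal((10, 3, 3, 2))
            _, _, p = roi_fwe_smallvolume(a, b, roi, n_perm=1024)
            hits += p <= 0.05
        assert hits / 40 > 0.9

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_fwe_smallvolume(
                np.zeros((5, 2, 2, 2)), np.zeros((5, 2, 2, 2)),
                np.zeros((2, 2, 2), bool),
            )


class TestRoiMean:
    def test_constant_difference_exact(self):
        roi = np.zeros((4, 4, 2), bool)
        roi[1:3, 1:3, :] = True
        diffs = np.full((6, 4, 4, 2), 0.37)
        np.testing.assert_allclose(
            roi_mean_change(diffs, roi), np.full(6, 0.37), rtol=1e-15
        )

    def test_single_voxel_roi(self):
        rng = np.random.default_rng(7)
        diffs = rng.standard_normal((5, 3, 3, 2))
        roi = np.zeros((3, 3, 2), bool)
        roi[2, 1, 0] = True
        np.testing.assert_array_equal(
            roi_mean_change(diffs, roi), diffs[:, 2, 1, 0]
        )

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(8)
        diffs = rng.standard_normal((7, 5, 4, 3))
        roi = rng.random((5, 4, 3)) > 0.5
        means = roi_mean_change(diffs, roi)
        for s in range(7):
            vals = [diffs[s][idx] for idx in zip(*np.nonzero(roi))]
            assert means[s] == pytest.approx(np.mean(vals), abs=1e-12)


class TestRegression:
    def test_collinear_gives_r2_one(self):
        x = np.arange(10.0)
        slope, intercept, r2, p = regress_change_on_covariate(x, 3 * x + 1)
        assert slope == pytest.approx(3.0)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_gives_r2_zero(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # symmetric, zero covariance
        _, _, r2, _ = regress_change_on_covariate(x, y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            regress_change_on_covariate(np.ones(5), np.arange(5.0))


class TestInteraction:
    @staticmethod
    def _table(values):
        import pandas as pd

        rows = []
        for s, cells in enumerate(values):
            for (cond, tp), v in zip(
                [("vaccine", "baseline"), ("vaccine", "4h"),
                 ("placebo", "baseline"), ("placebo", "4h")], cells
            ):
                rows.append(dict(subject=f"s{s}", condition=cond,
                                 timepoint=tp, outcome=v))
        return pd.DataFrame(rows)

    def test_zero_difference_of_differences(self):
        table = self._table([[1.0, 3.0, 5.0, 7.0]] * 4)
        # add subject-level offsets: interaction remains exactly zero
        F, df1, df2, p = repeated_measures_interaction(table, "outcome")
        assert F == 0.0

    def test_matches_rm_anova_oracle(self):
        pytest.importorskip("statsmodels")
        from statsmodels.stats.anova import AnovaRM

        table = self._table(
            [[10.0, 25.0, 12.0, 15.0],
             [8.0, 30.0, 9.0, 11.0],
             [12.0, 20.0, 14.0, 18.0],
             [15.0, 33.0, 13.0, 16.0],
             [9.0, 22.0, 10.0, 17.0]]
        )
        F, df1, df2, p = repeated_measures_interaction(table, "outcome")
        res = AnovaRM(
            table, "outcome", "subject", within=["condition", "timepoint"]
        ).fit()
        row = res.anova_table.loc["condition:timepoint"]
        assert F == pytest.approx(row["F Value"], abs=1e-10)
        assert p == pytest.approx(row["Pr > F"], abs=1e-10)
        assert (df1, df2) == (int(row["Num DF"]), int(row["Den DF"]))

    def test_incomplete_design_rejected(self):
        table = self._table([[1.0, 2.0, 3.0, 4.0]] * 3).iloc[:-1]
        with pytest.raises(ValueError):
            repeated_measures_interaction(table, "outcome")


class TestContrastLogic:
    def test_grand_mean_scaling_exact_and_idempotent(self):
        rng = np.random.default_rng(9)
        vol = rng.random((6, 6, 4)) * 30 + 10
        mask = rng.random((6, 6, 4)) > 0.3
        scaled = grand_mean_scale(vol, mask, target=50.0)
        assert scaled[mask].mean() == pytest.approx(50.0, abs=1e-12)
        twice = grand_mean_scale(scaled, mask, target=50.0)
        np.testing.assert_allclose(twice, scaled, rtol=1e-12)

    def test_grand_mean_scale_invariant_to_input_scale(self):
        rng = np.random.default_rng(10)
        vol = rng.random((5, 5, 3)) + 0.5
        mask = np.ones((5, 5, 3), bool)
        a = grand_mean_scale(vol, mask)
        b = grand_mean_scale(vol * 17.0, mask)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_exclusive_mask_passthrough_and_removal(self):
        shape = (5, 5, 3)
        t = np.full(shape, 4.0)
        mask = np.ones(shape, bool)
        stat = StatMap(t=t, df=19, n_pairs=20, mask=mask)
        quiet = StatMap(t=np.zeros(shape), df=19, n_pairs=20, mask=mask)
        loud = StatMap(t=np.full(shape, 50.0), df=19, n_pairs=20, mask=mask)
        assert exclusive_mask(stat, quiet).mask.all()
        assert not exclusive_mask(stat, loud).mask.any()

    def test_exclusive_mask_matches_per_voxel_oracle(self):
        rng = np.random.default_rng(11)
        shape = (6, 5, 4)
        stat = StatMap(t=rng.standard_normal(shape) * 3, df=19, n_pairs=20,
                       mask=np.ones(shape, bool))
        ctrl = StatMap(t=rng.standard_normal(shape) * 3, df=19, n_pairs=20,
                       mask=np.ones(shape, bool))
        out = exclusive_mask(stat, ctrl, p_mask=0.005)
        t_crit = stats.t.isf(0.005, 19)
        for idx in np.ndindex(*shape):
            expected = ctrl.t[idx] <= t_crit
            assert out.mask[idx] == expected
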