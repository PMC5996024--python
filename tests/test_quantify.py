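"""Quantification contracts: band projections, patch ratios, normalisations,
ROUT outlier handling and the group-comparison statistics."""

import numpy as np
import pytest

from ciliaquant.detection import VoxelGrid
from ciliaquant.quantify import (
    ZBandSpec,
    band_projection,
    chi2_trend,
    compare_groups,
    dunn_posthoc,
    fold_change_counts,
    neighbour_normalised_intensity,
    patch_ratio,
    remove_outliers_rout,
    select_nearest_neighbours,
)

VOX = (0.23, 0.1, 0.1)


class TestBandProjection:
    def test_identical_planes_sum_to_six_times_mean(self):
        grid = VoxelGrid(np.full((12, 8, 8), 3.0), VOX)
        proj, truncated = band_projection(grid, ZBandSpec(), anchor_z_um=6 * 0.23)
        assert not truncated
        np.testing.assert_allclose(proj, 18.0)

    def test_single_nonzero_plane_inside_band(self):
        data = np.zeros((12, 4, 4))
        data[7] = 5.0
        grid = VoxelGrid(data, VOX)
        proj, _ = band_projection(grid, ZBandSpec(), anchor_z_um=6 * 0.23)  # band 4..9
        np.testing.assert_allclose(proj, 5.0)

    def test_linear_ramp_equals_closed_form(self):
        nz = 15
        data = np.arange(nz, dtype=float)[:, None, None] * np.ones((1, 3, 3))
        grid = VoxelGrid(data, VOX)
        anchor = 7
        proj, _ = band_projection(grid, ZBandSpec(), anchor_z_um=(anchor + 0.5) * 0.23)
        # window = anchor-2 .. anchor+3 (documented even-count rounding)
        expected = sum(range(anchor - 2, anchor + 4))
        np.testing.assert_allclose(proj, expected)

    def test_truncated_band_flagged(self):
        grid = VoxelGrid(np.ones((4, 3, 3)), VOX)
        proj, truncated = band_projection(grid, ZBandSpec(), anchor_z_um=0.1)
        assert truncated
        np.testing.assert_allclose(proj, 4.0)  # planes 0..3 available of 6

    def test_anchor_outside_stack_raises(self):
        grid = VoxelGrid(np.ones((4, 3, 3)), VOX)
        with pytest.raises(ValueError):
            band_projection(grid, ZBandSpec(), anchor_z_um=5.0)


class TestPatchRatio:
    def test_uniform_image_ratio_one(self):
        img = np.full((20, 20), 4.2)
        cell = np.ones_like(img, bool)
        patch = np.zeros_like(cell)
        patch[5:10, 5:10] = True
        assert patch_ratio(img, patch, cell) == pytest.approx(1.0)

    def test_twofold_patch(self):
        img = np.ones((10, 10))
        cell = np.ones_like(img, bool)
        patch = np.zeros_like(cell)
        patch[:3, :3] = True
        img[patch] = 2.0
        assert patch_ratio(img, patch, cell) == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 5, size=(15, 15))
        cell = np.ones_like(img, bool)
        patch = np.zeros_like(cell)
        patch[2:6, 2:6] = True
        assert patch_ratio(img * 13.0, patch, cell) == pytest.approx(
            patch_ratio(img, patch, cell)
        )

    def test_patch_outside_cell_raises(self):
        img = np.ones((5, 5))
        cell = np.zeros_like(img, bool)
        cell[:3] = True
        patch = np.zeros_like(cell)
        patch[4, 4] = True
        with pytest.raises(ValueError, match="contained"):
            patch_ratio(img, patch, cell)

    def test_empty_rest_region_nan_with_warning(self):
        img = np.ones((4, 4))
        cell = np.ones_like(img, bool)
        with pytest.warns(UserWarning, match="empty"):
            assert np.isnan(patch_ratio(img, cell.copy(), cell))

    def test_generator_ratio_recovery(self):
        from ciliaquant import SceneSpec, render_stack

        spec = SceneSpec(actin_ratio_apical=1.8, seed=4)
        channels, truth = render_stack(spec)
        proj, _ = band_projection(channels["actin"], ZBandSpec(), truth.apical_z_um)
        cm, pm = truth.masks(1)
        assert patch_ratio(proj, pm, cm) == pytest.approx(1.8, abs=0.05)


class TestNormalisations:
    def test_identical_intensities_give_one(self):
        fc, flagged = neighbour_normalised_intensity(5.0, [5.0, 5.0, 5.0])
        assert fc == pytest.approx(1.0) and not flagged

    def test_halved_cell(self):
        fc, _ = neighbour_normalised_intensity(2.0, [4.0, 4.0, 4.0])
        assert fc == pytest.approx(0.5)

    def test_fewer_neighbours_flagged(self):
        with pytest.warns(UserWarning):
            fc, flagged = neighbour_normalised_intensity(3.0, [6.0])
        assert flagged and fc == pytest.approx(0.5)

    def test_neighbour_selection_distance_then_id(self):
        centroids = {0: (0, 0), 1: (1, 0), 2: (0, 1), 3: (2, 0), 4: (5, 5)}
        transfected = {0: True, 3: False}
        chosen, flagged = select_nearest_neighbours(0, centroids, transfected, k=3)
        assert chosen == [1, 2, 3] and not flagged  # tie 1 vs 2 broken by id

    def test_randomised_field_matches_table_arithmetic(self):
        rng = np.random.default_rng(8)
        values = {cid: float(v) for cid, v in enumerate(rng.uniform(10, 20, 6))}
        centroids = {cid: (float(rng.uniform(0, 10)), float(rng.uniform(0, 10))) for cid in values}
        chosen, _ = select_nearest_neighbours(2, centroids, {}, k=3)
        fc, _ = neighbour_normalised_intensity(values[2], [values[c] for c in chosen])
        assert fc == pytest.approx(values[2] / np.mean([values[c] for c in chosen]))

    def test_fold_change_identity_and_scale_freedom(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(30, 50).astype(float)
        fc = fold_change_counts(counts, counts)
        assert fc.mean() == pytest.approx(1.0, abs=0.001)
        fc2 = fold_change_counts(counts * 2, counts * 2)
        np.testing.assert_allclose(fc2, fc)

    def test_fold_change_single_cell(self):
        assert fold_change_counts([15.0], [30.0, 30.0])[0] == pytest.approx(0.5)

    def test_zero_reference_mean_raises(self):
        with pytest.raises(ValueError):
            fold_change_counts([1.0], [0.0, 0.0])


class TestRout:
    def test_clean_gaussian_rarely_removes(self):
        removals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            _, removed = remove_outliers_rout(rng.normal(0, 1, 100), 1.0)
            removals.append(len(removed))
        assert max(removals) <= 5

    def test_ten_sigma_contaminant_removed(self):
        rng = np.random.default_rng(2)
        x = np.append(rng.normal(0, 1, 99), 10.0)
        kept, removed = remove_outliers_rout(x, 1.0)
        assert 10.0 in removed and 10.0 not in kept

    def test_constant_sample_untouched(self):
        kept, removed = remove_outliers_rout(np.full(20, 3.0), 1.0)
        assert len(removed) == 0 and len(kept) == 20

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            kept, removed = remove_outliers_rout([1.0] * 5, 1.0)
        assert len(removed) == 0

    def test_q_zero_removes_nothing_and_monotone_in_q(self):
        rng = np.random.default_rng(3)
        x = np.append(rng.normal(0, 1, 95), [6, 7, 8, 9, 10.0])
        _, removed0 = remove_outliers_rout(x, 0.0)
        assert len(removed0) == 0
        n_removed = [len(remove_outliers_rout(x, q)[1]) for q in (0.1, 1.0, 5.0)]
        assert n_removed == sorted(n_removed)


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        x = list(range(20))
        res = compare_groups({"a": x, "b": x})
        assert res["test"] == "mann-whitney"
        assert res["p_value"] > 0.9
        assert res["statistic"] == pytest.approx(20 * 20 / 2)  # U at its null centre

    def test_shifted_groups_power(self):
        """Two groups 2 pooled-SD apart, n=30: p < 0.001 in >= 95% of 100
        simulations (reduced-rep version of the calibration example)."""
        rng = np.random.default_rng(4)
        hits = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(0, 1, 30)
            b = rng.normal(2, 1, 30)
            hits += compare_groups({"a": a, "b": b})["p_value"] < 0.001
        assert hits / reps >= 0.95

    def test_null_type_one_error(self):
        rng = np.random.default_rng(5)
        rej = 0
        reps = 500
        for _ in range(reps):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 15)
            rej += compare_groups({"a": a, "b": b})["p_value"] < 0.05
        assert 0.03 <= rej / reps <= 0.08

    def test_three_groups_runs_dunn(self):
        rng = np.random.default_rng(6)
        res = compare_groups(
            {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20), "c": rng.normal(3, 1, 20)}
        )
        assert res["test"] == "kruskal-dunn"
        pw = res["pairwise"]
        assert len(pw) == 3
        ac = pw[(pw.group_a == "a") & (pw.group_b == "c")].iloc[0]
        ab = pw[(pw.group_a == "a") & (pw.group_b == "b")].iloc[0]
        assert ac.p_adjusted < 0.01 < ab.p_adjusted
        assert (pw.p_adjusted >= pw.p_value - 1e-12).all()

    def test_degenerate_group_flagged(self):
        with pytest.warns(UserWarning, match="n < 3"):
            res = compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        assert res["degenerate_groups"] == ["a"]

    def test_dunn_bonferroni_factor(self):
        rng = np.random.default_rng(7)
        groups = {g: rng.normal(0, 1, 12) for g in "abcd"}
        pw = dunn_posthoc(groups)
        assert len(pw) == 6
        np.testing.assert_allclose(
            pw.p_adjusted, np.minimum(1.0, pw.p_value * 6), atol=1e-12
        )


class TestChi2Trend:
    def test_no_trend_high_p(self):
        table = np.array([[10, 10, 10, 10], [10, 10, 10, 10]])
        res = chi2_trend(table)
        assert res["p_value"] == pytest.approx(1.0)

    def test_monotone_trend_detected(self):
        table = np.array([[5, 10, 20, 40], [40, 20, 10, 5]])
        res = chi2_trend(table)
        assert res["p_value"] < 1e-6 and res["z"] > 0

    def test_matches_hand_computation(self):
        # 2x2 case: the trend statistic reduces to the standard chi-squared
        # with one degree of freedom (no continuity correction)
        table = np.array([[12, 5], [8, 15]])
        res = chi2_trend(table)
        from scipy.stats import chi2_contingency

        expected = chi2_contingency(table, correction=False).statistic
        assert res["statistic"] == pytest.approx(expected, rel=1e-9)
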