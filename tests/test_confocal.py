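import numpy as np
import pytest

from azquant import confocal as conf
from azquant.synth import SceneSpec, render_confocal_field, simulate_confocal_cohort
from oracles import flood_fill_count

PX = 100.0


class TestBackgroundSubtraction:
    def test_constant_field_subtracts_to_zero(self):
        out = conf.subtract_local_background(np.full((64, 64), 7.0), PX)
        assert np.all(out == 0)

    def test_impulse_survives_background_removal(self):
        img = np.full((64, 64), 10.0)
        img[32, 32] += 100.0
        out = conf.subtract_local_background(img, PX)
        # the impulse is attenuated only by its own share of the footprint mean
        assert out[32, 32] > 90.0
        assert out[5, 5] < 1.0

    def test_puncta_on_linear_ramp_recovered(self):
        # 50 nm/px so each punctum is small relative to the 1.4-um window
        scene = SceneSpec(shape=(256, 256), pixel_size_nm=50.0, psf_sigma_nm=0.0, seed=4)
        # keep puncta clear of each other's and the border's background window
        stack, truth = render_confocal_field(
            scene, 10, 100.0, punctum_radius_px=2.5, background=lambda yy, xx: 0.1 * xx,
            min_separation_px=36.0, edge_margin_px=20.0,
        )
        protein = conf.subtract_local_background(stack.frame(0, 1), 50.0)
        marker = conf.subtract_local_background(stack.frame(0, 0), 50.0)
        rois = conf.define_rois(marker, 50.0, min_area_um2=0.04)
        table, _ = conf.measure_roi_means(protein, rois)
        assert rois.n_rois == 10
        np.testing.assert_allclose(table.mean_intensity, 100.0, rtol=0.05)

    def test_too_small_window_rejected(self):
        with pytest.raises(ValueError):
            conf.subtract_local_background(np.zeros((32, 32)), pixel_size_nm=1400.0)


class TestROIDefinition:
    def test_planted_puncta_counted(self):
        scene = SceneSpec(shape=(160, 160), pixel_size_nm=PX, psf_sigma_nm=0.0, seed=5)
        stack, _ = render_confocal_field(scene, 10, 100.0)
        rois = conf.define_rois(stack.frame(0, 0), PX)
        assert rois.n_rois == 10

    def test_touching_puncta_merge_into_one_roi(self):
        img = np.zeros((40, 40))
        img[10:16, 10:16] = 100.0
        img[16:22, 16:22] = 100.0  # 8-connected through the corner
        rois = conf.define_rois(img, PX, min_area_um2=0.0, max_area_um2=np.inf)
        assert rois.n_rois == 1

    def test_count_matches_flood_fill_oracle(self, rng):
        for _ in range(50):
            mask = rng.random((32, 32)) < 0.25
            rois = conf.define_rois(mask.astype(float), PX, threshold_method=0.5, min_area_um2=0.0, max_area_um2=np.inf)
            assert rois.n_rois == flood_fill_count(mask)


class TestROIMeans:
    def test_uniform_protein_value(self):
        scene = SceneSpec(shape=(160, 160), pixel_size_nm=PX, psf_sigma_nm=0.0, seed=5)
        stack, _ = render_confocal_field(scene, 8, punctum_intensities=50.0)
        rois = conf.define_rois(stack.frame(0, 0), PX)
        table, image_mean = conf.measure_roi_means(stack.frame(0, 1), rois)
        np.testing.assert_allclose(table.mean_intensity, 50.0)
        assert image_mean == 50.0

    def test_two_population_intensities_recovered(self):
        scene = SceneSpec(shape=(200, 200), pixel_size_nm=PX, psf_sigma_nm=0.0, seed=6)
        intensities = [40.0] * 5 + [120.0] * 5
        stack, truth = render_confocal_field(scene, 10, intensities)
        rois = conf.define_rois(stack.frame(0, 0), PX)
        table, _ = conf.measure_roi_means(stack.frame(0, 1), rois)
        assert sorted(np.round(table.mean_intensity.unique(), 6)) == [40.0, 120.0]

    def test_single_pixel_roi_returns_that_pixel(self):
        img = np.arange(16.0).reshape(4, 4)
        mask = np.zeros((4, 4), dtype=int)
        mask[2, 3] = 1
        import pandas as pd

        rois = conf.ROISet(mask, pd.DataFrame({"roi_id": [1], "area_um2": [0.01], "centroid_row": [2], "centroid_col": [3]}))
        table, _ = conf.measure_roi_means(img, rois)
        assert table.mean_intensity.iloc[0] == img[2, 3]

    def test_empty_roiset_flagged(self):
        rois = conf.define_rois(np.zeros((16, 16)), PX)
        with pytest.warns(UserWarning, match="no ROIs"):
            _, image_mean = conf.measure_roi_means(np.ones((16, 16)), rois)
        assert np.isnan(image_mean)


class TestNormalization:
    def test_single_values(self):
        table, _ = conf.normalize_to_control([80.0, 52.0], ["control", "KO"], ["c1", "c1"])
        assert table.loc[table.group == "KO", "normalized"].iloc[0] == pytest.approx(0.65)

    def test_control_mean_is_one_per_culture(self, rng):
        values = rng.uniform(10, 50, 20)
        cultures = ["c1"] * 10 + ["c2"] * 10
        table, summary = conf.normalize_to_control(values, ["control"] * 20, cultures)
        assert summary.loc[summary.group == "control", "mean"].iloc[0] == pytest.approx(1.0)

    def test_missing_control_culture_rejected(self):
        with pytest.raises(ValueError, match="without"):
            conf.normalize_to_control([1.0, 2.0], ["KO", "KO"], ["c1", "c1"])

    def test_planted_cohort_ratio_recovered(self):
        scene = SceneSpec(shape=(160, 160), pixel_size_nm=PX, psf_sigma_nm=0.0, seed=9)
        records, _ = simulate_confocal_cohort(
            scene, {"control": 1.0, "KO": 0.65}, n_cultures=3, images_per_group=3, seed=9
        )
        values, groups, cultures = [], [], []
        for rec in records:
            rois = conf.define_rois(rec["stack"].frame(0, 0), PX)
            _, m = conf.measure_roi_means(rec["stack"].frame(0, 1), rois)
            values.append(m)
            groups.append(rec["group"])
            cultures.append(rec["culture"])
        _, summary = conf.normalize_to_control(values, groups, cultures, control_group="control")
        assert summary.loc[summary.group == "KO", "mean"].iloc[0] == pytest.approx(0.65, rel=0.03)


class TestPearson:
    def test_identical_channels_correlate_perfectly(self, rng):
        a = rng.random((32, 32))
        assert conf.pearson_colocalization(a, a) == pytest.approx(1.0)

    def test_inverted_channel_anticorrelates(self, rng):
        a = rng.random((32, 32))
        assert conf.pearson_colocalization(a, -a) == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self, rng):
        a = rng.random((100, 100))
        b = rng.random((100, 100))
        assert abs(conf.pearson_colocalization(a, b)) < 3 / np.sqrt(a.size)

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r = conf.pearson_colocalization(np.ones((8, 8)), np.random.default_rng(0).random((8, 8)))
        assert np.isnan(r)

    def test_mask_restricts_the_computation(self, rng):
        a = rng.random((16, 16))
        b = a.copy()
        b[:8] = rng.random((8, 16))  # decorrelate the unmasked half
        mask = np.zeros((16, 16), dtype=bool)
        mask[8:] = True
        assert conf.pearson_colocalization(a, b, mask) == pytest.approx(1.0)
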