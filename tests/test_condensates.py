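import math

import numpy as np
import pytest

from azquant import condensates as cond
from azquant.synth import DropletSpec, FusionEventSpec, SceneSpec, render_droplet_movie
from oracles import relaxation_gridsearch

PX = 100.0  # nm per pixel


def disk_frame(diameters_um, shape=None, intensity=100.0):
    """Noiseless frame with disks of the given diameters, spaced apart."""
    if shape is None:
        shape = (128, 30 + 30 * len(diameters_um))
    scene = SceneSpec(shape=shape, pixel_size_nm=PX, psf_sigma_nm=0.0, seed=0)
    droplets = []
    x = 20.0
    for d in diameters_um:
        droplets.append(DropletSpec(center_xy=(x, shape[0] / 2), radius_nm=d * 500.0, intensity=intensity))
        x += 30.0
    stack, truth = render_droplet_movie(scene, droplets, n_frames=1)
    return stack.frame(0), truth


class TestSegmentation:
    def test_minimum_diameter_cutoff(self):
        frame, _ = disk_frame([0.8, 1.2, 2.0])
        objs = cond.segment_condensates(frame, PX, min_diameter_um=1.0)
        assert len(objs) == 2

    def test_measured_area_close_to_analytic(self):
        frame, _ = disk_frame([1.2])
        (obj,) = cond.segment_condensates(frame, PX)
        assert obj.area_um2 == pytest.approx(math.pi * 0.6**2, rel=0.03)
        assert obj.equivalent_diameter_um == pytest.approx(2 * math.sqrt(obj.area_um2 / math.pi), rel=1e-12)

    def test_empty_frame_yields_no_objects(self):
        assert cond.segment_condensates(np.zeros((64, 64)), PX) == []

    def test_objects_ordered_by_centroid(self):
        frame, _ = disk_frame([1.5, 1.5, 1.5])
        objs = cond.segment_condensates(frame, PX)
        cols = [o.centroid_rc[1] for o in objs]
        assert cols == sorted(cols)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            cond.segment_condensates(np.ones((8, 8)), 0.0)


class TestDropletPositiveClassification:
    def test_spherical_droplet_positive(self):
        frame, _ = disk_frame([1.5])
        assert cond.classify_cell_droplet_positive(frame, PX) is True

    def test_elongated_objects_fail_sphericity_gate(self):
        img = np.zeros((64, 64))
        img[30:34, 10:40] = 100.0  # AR ~ 7.5, area > 1 um diameter equivalent
        assert cond.classify_cell_droplet_positive(img, PX) is False

    def test_subdiameter_droplets_negative(self):
        frame, _ = disk_frame([0.8])
        assert cond.classify_cell_droplet_positive(frame, PX) is False

    def test_cohort_percent_positive_matches_ground_truth(self):
        rng = np.random.default_rng(7)
        planted = [True] * 18 + [False] * 3
        rng.shuffle(planted)
        positive = 0
        for i, has_droplet in enumerate(planted):
            frame, _ = disk_frame([1.4] if has_droplet else [0.6])
            positive += cond.classify_cell_droplet_positive(frame, PX)
        assert positive / len(planted) == pytest.approx(18 / 21)


class TestCountAndSize:
    def test_counts_per_image(self):
        frames = [disk_frame([1.2, 1.5, 2.0, 1.1, 1.3])[0] for _ in range(3)]
        counts, sizes = cond.count_and_size_condensates(frames, PX)
        assert counts.n_condensates.tolist() == [5, 5, 5]
        assert len(sizes) == 15

    def test_planted_areas_recovered(self):
        diam = [1.2, 1.6, 2.0]
        frame, _ = disk_frame(diam)
        _, sizes = cond.count_and_size_condensates([frame], PX)
        expected = sorted(math.pi * (d / 2) ** 2 for d in diam)
        np.testing.assert_allclose(sorted(sizes.area_um2), expected, rtol=0.05)

    def test_raising_cutoff_drops_counts(self):
        frame, _ = disk_frame([1.2, 1.6, 2.2])
        counts1, _ = cond.count_and_size_condensates([frame], PX, min_diameter_um=1.0)
        counts2, _ = cond.count_and_size_condensates([frame], PX, min_diameter_um=2.0)
        assert counts1.n_condensates.iloc[0] == 3
        assert counts2.n_condensates.iloc[0] == 1


class TestTracking:
    def test_drifting_droplet_stays_one_track(self):
        scene = SceneSpec(shape=(96, 96), pixel_size_nm=PX, psf_sigma_nm=0.0, seed=0)
        droplets = [DropletSpec(center_xy=(20, 48), radius_nm=700, velocity_px_per_frame=(1.0, 0.0))]
        stack, _ = render_droplet_movie(scene, droplets, n_frames=20)
        result = cond.track_condensates(stack, max_link_distance_nm=300)
        assert len(result.tracks) == 1
        assert result.tracks[0].last_frame == 19

    def test_static_objects_tracked_as_identity(self, rng):
        scene = SceneSpec(shape=(256, 256), pixel_size_nm=PX, psf_sigma_nm=0.0, seed=3)
        from azquant.synth.droplets import random_droplet_field

        droplets = random_droplet_field(scene, 10, rng)
        stack, truth = render_droplet_movie(scene, droplets, n_frames=5)
        result = cond.track_condensates(stack, max_link_distance_nm=300)
        assert len(result.tracks) == 10
        assert all(len(t.objects) == 5 for t in result.tracks)
        assert result.candidate_events == []

    def test_merge_topology_yields_fusion_candidate(self):
        scene = SceneSpec(shape=(96, 96), pixel_size_nm=PX, psf_sigma_nm=0.0, seed=0)
        parents = [
            DropletSpec(center_xy=(32, 48), radius_nm=700),
            DropletSpec(center_xy=(48, 48), radius_nm=700),
        ]
        event = FusionEventSpec(parent_ids=(0, 1), fusion_frame=6, tau_s=7.41)
        stack, _ = render_droplet_movie(scene, parents, [event], n_frames=12)
        result = cond.track_condensates(stack, max_link_distance_nm=900)
        kinds = [(c.kind, c.frame) for c in result.candidate_events]
        assert kinds == [("fusion", 6)]
        ended = [t for t in result.tracks if t.last_frame == 5]
        assert len(ended) == 2


class TestEventConfirmation:
    @staticmethod
    def fusion_movie(child_death_frame=None, n_frames=60):
        scene = SceneSpec(shape=(96, 96), pixel_size_nm=PX, psf_sigma_nm=0.0, frame_interval_s=1.0, seed=0)
        parents = [
            DropletSpec(center_xy=(32, 48), radius_nm=700),
            DropletSpec(center_xy=(48, 48), radius_nm=700),
        ]
        event = FusionEventSpec(parent_ids=(0, 1), fusion_frame=6, tau_s=7.41, child_death_frame=child_death_frame)
        stack, truth = render_droplet_movie(scene, parents, [event], n_frames=n_frames)
        return cond.track_condensates(stack, max_link_distance_nm=900)

    def test_stable_product_confirmed(self):
        confirmed = cond.detect_fusion_fission(self.fusion_movie(child_death_frame=6 + 45), 1.0, stability_s=30)
        assert [c.kind for c in confirmed] == ["fusion"]

    def test_short_lived_product_rejected(self):
        confirmed = cond.detect_fusion_fission(self.fusion_movie(child_death_frame=6 + 20), 1.0, stability_s=30)
        assert confirmed == []

    def test_fusion_and_fission_both_recovered(self):
        scene = SceneSpec(shape=(128, 128), pixel_size_nm=PX, psf_sigma_nm=0.0, frame_interval_s=1.0, seed=0)
        droplets = [
            # fusing pair
            DropletSpec(center_xy=(28, 30), radius_nm=700),
            DropletSpec(center_xy=(44, 30), radius_nm=700),
            # fission: parent dies, two offspring appear
            DropletSpec(center_xy=(80, 90), radius_nm=900, death_frame=9),
            DropletSpec(center_xy=(73, 90), radius_nm=630, birth_frame=10),
            DropletSpec(center_xy=(88, 90), radius_nm=640, birth_frame=10),
        ]
        event = FusionEventSpec(parent_ids=(0, 1), fusion_frame=6, tau_s=7.41)
        stack, _ = render_droplet_movie(scene, droplets, [event], n_frames=60)
        result = cond.track_condensates(stack, max_link_distance_nm=900)
        confirmed = cond.detect_fusion_fission(result, 1.0, stability_s=30)
        found = sorted((c.kind, c.frame) for c in confirmed)
        assert [k for k, _ in found] == ["fission", "fusion"]
        assert abs(dict(found)["fusion"] - 6) <= 1
        assert abs(dict(found)["fission"] - 10) <= 1


class TestRelaxationFit:
    def test_recovers_published_curve_parameters(self):
        """Noiseless samples of 0.93 + 1.48 exp(-t/7.41) give the
        parameters back to better than 1%."""
        t = np.arange(0, 41, 1.0)
        ar = 0.93 + 1.48 * np.exp(-t / 7.41)
        fit = cond.fit_relaxation(t, ar)
        assert fit.tau_s == pytest.approx(7.41, rel=0.01)
        assert fit.ar_inf == pytest.approx(0.93, rel=0.01)
        assert fit.ar_0 == pytest.approx(2.41, rel=0.01)
        assert fit.sub_unity_asymptote

    def test_constant_series_flagged_degenerate(self):
        fit = cond.fit_relaxation(np.arange(5.0), np.ones(5))
        assert fit.degenerate
        assert fit.ar_0 == fit.ar_inf == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cond.fit_relaxation([0, 1, 2], [2.0, 1.5, 1.2])

    def test_matches_gridsearch_oracle_on_noiseless_data(self):
        t = np.arange(0, 41, 1.0)
        ar = 1.05 + 1.3 * np.exp(-t / 5.2)
        fit = cond.fit_relaxation(t, ar)
        tau_grid = np.arange(3.0, 8.01, 0.05)
        inf_grid = np.arange(0.9, 1.2001, 0.01)
        tau_star, inf_star = relaxation_gridsearch(t, ar, tau_grid, inf_grid)
        assert abs(fit.tau_s - tau_star) <= 0.05
        assert abs(fit.ar_inf - inf_star) <= 0.01

    def test_noisy_tau_recovery_median_error_under_10_percent(self):
        t = np.arange(0, 41, 1.0)
        clean = 0.93 + 1.48 * np.exp(-t / 7.41)
        errors = []
        for seed in range(50):
            noisy = clean + np.random.default_rng(seed).normal(0, 0.05, size=t.size)
            fit = cond.fit_relaxation(t, noisy)
            errors.append(abs(fit.tau_s - 7.41) / 7.41)
        assert np.median(errors) < 0.10
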