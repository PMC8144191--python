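import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from azquant import sted
from azquant.io import ImageStack
from azquant.synth import SceneSpec, SideViewSpec, render_sideview_image, simulate_sideview_profile
from azquant.synth.sideview import true_profile_line
from oracles import moving_average_bruteforce

PX = 22.5  # nm per pixel, the STED sampling pitch

STED_SCENE = dict(shape=(96, 96), pixel_size_nm=PX, psf_sigma_nm=30.0)


def centred_line(angle=0.0, shape=(96, 96)):
    return sted.ProfileLine(center_xy=((shape[1] - 1) / 2, (shape[0] - 1) / 2), angle_rad=angle)


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        stack = ImageStack(np.full((64, 64), 7.0), pixel_size_nm=PX)
        profile = sted.extract_profile(stack, centred_line(angle=0.4, shape=(64, 64)))
        np.testing.assert_allclose(profile.values, 7.0)

    @pytest.mark.parametrize("angle", [0.0, 0.35, 1.2])
    def test_gaussian_peak_located_within_one_pixel(self, angle):
        scene = SceneSpec(**STED_SCENE, seed=0)
        spec = SideViewSpec(protein_offset_nm=0.0, axis_angle_rad=angle)
        stack, _ = render_sideview_image(scene, spec)
        profile = sted.extract_profile(stack, centred_line(angle))
        marker = profile.channel(1)
        assert abs(profile.positions_nm[int(np.argmax(marker))]) <= PX

    def test_reversing_the_line_flips_positions(self):
        scene = SceneSpec(**STED_SCENE, seed=1)
        spec = SideViewSpec(protein_offset_nm=45.0)
        stack, _ = render_sideview_image(scene, spec)
        fwd = sted.extract_profile(stack, centred_line(0.0))
        rev = sted.extract_profile(stack, centred_line(math.pi))
        np.testing.assert_allclose(fwd.values, rev.values[::-1], atol=1e-9)

    def test_line_exiting_image_rejected(self):
        stack = ImageStack(np.zeros((10, 10)), pixel_size_nm=PX)
        with pytest.raises(ValueError, match="exits"):
            sted.extract_profile(stack, sted.ProfileLine(center_xy=(5, 5), angle_rad=0.0))


class TestSmoothProfile:
    def test_impulse_box_filter(self):
        out = sted.smooth_profile(np.array([0.0, 0, 1, 0, 0]), 5)
        assert out[2] == pytest.approx(0.2)

    def test_constant_profile_unchanged(self):
        np.testing.assert_allclose(sted.smooth_profile(np.full(11, 3.3), 5), 3.3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            sted.smooth_profile(np.zeros(5), 4)

    @given(
        hnp.arrays(np.float64, st.integers(5, 60), elements=st.floats(-1e3, 1e3)),
        st.sampled_from([1, 3, 5, 7]),
    )
    def test_equals_bruteforce_oracle(self, values, window):
        np.testing.assert_allclose(
            sted.smooth_profile(values, window),
            moving_average_bruteforce(values, window),
            rtol=1e-12,
            atol=1e-9,
        )


class TestMeasurePeaks:
    def test_offset_measured_to_pixel_resolution(self):
        profile, _ = simulate_sideview_profile(SideViewSpec(protein_offset_nm=45.0), pixel_size_nm=PX)
        peaks = sted.measure_peaks(profile, 1, 2)
        assert peaks.peak_distance_nm == pytest.approx(45.0, abs=PX)

    def test_brighter_out_of_window_decoy_ignored(self):
        spec = SideViewSpec(protein_offset_nm=0.0, protein_peak_intensity=100.0, decoy_peaks=((250.0, 400.0),))
        profile, _ = simulate_sideview_profile(spec, pixel_size_nm=PX)
        peaks = sted.measure_peaks(profile, 1, 2, window_nm=100.0)
        assert peaks.peak_distance_nm <= 100.0

    def test_window_guarantee_on_randomised_decoys(self, rng):
        for _ in range(100):
            spec = SideViewSpec(
                protein_offset_nm=float(rng.uniform(-90, 90)),
                decoy_peaks=((float(rng.uniform(130, 400)) * rng.choice([-1, 1]), float(rng.uniform(200, 800))),),
            )
            profile, _ = simulate_sideview_profile(spec, pixel_size_nm=PX)
            peaks = sted.measure_peaks(profile, 1, 2)
            assert peaks.peak_distance_nm <= 100.0 + 1e-9

    def test_zero_offset_peaks_coincide(self):
        profile, _ = simulate_sideview_profile(SideViewSpec(protein_offset_nm=0.0), pixel_size_nm=PX)
        peaks = sted.measure_peaks(profile, 1, 2)
        assert peaks.peak_distance_nm == 0.0


class TestQualification:
    def test_default_synthetic_sideview_qualifies(self):
        scene = SceneSpec(**STED_SCENE, seed=2)
        spec = SideViewSpec(axis_angle_rad=0.3)
        stack, _ = render_sideview_image(scene, spec)
        line = true_profile_line(scene, spec)
        result = sted.qualify_sideview(stack.frame(0, 0), stack.frame(0, 1), line, PX)
        assert result.passed, result.reasons
        assert result.cloud_fwhm_nm > 300

    def test_narrow_vesicle_cloud_fails(self):
        scene = SceneSpec(**STED_SCENE, seed=2)
        spec = SideViewSpec(vesicle_cloud_width_nm=200.0, allow_unqualifiable=True)
        stack, _ = render_sideview_image(scene, spec)
        line = true_profile_line(scene, spec)
        result = sted.qualify_sideview(stack.frame(0, 0), stack.frame(0, 1), line, PX)
        assert not result.passed
        assert any("FWHM" in r for r in result.reasons)

    def test_marker_parallel_to_line_fails_orientation_gate(self):
        scene = SceneSpec(**STED_SCENE, seed=2)
        spec = SideViewSpec(axis_angle_rad=0.0)
        stack, _ = render_sideview_image(scene, spec)
        # probe along the bar instead of across it
        line = centred_line(angle=math.pi / 2)
        result = sted.qualify_sideview(stack.frame(0, 0), stack.frame(0, 1), line, PX)
        assert not result.passed
        assert any("perpendicular" in r for r in result.reasons)

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sted.qualify_sideview(np.zeros((10, 10)), np.zeros((12, 12)), centred_line(), PX)


class TestDensitySegmentation:
    @staticmethod
    def density_image(areas_um2, shape=(128, 128)):
        img = np.zeros(shape)
        x = 15
        for a in areas_um2:
            side = int(round(math.sqrt(a * 1e6) / PX))  # square of roughly the target area
            img[40 : 40 + side, x : x + side] = 100.0
            x += side + 12
        return img

    def test_size_filter_bounds(self):
        img = self.density_image([0.02, 0.1, 0.5])
        objs = sted.segment_marker_densities(img, PX)
        assert len(objs) == 1
        assert 0.04 <= objs[0].area_um2 <= 0.4

    def test_empty_image_yields_nothing(self):
        assert sted.segment_marker_densities(np.zeros((64, 64)), PX) == []

    def test_wide_filter_keeps_everything(self):
        img = self.density_image([0.02, 0.1, 0.5])
        objs = sted.segment_marker_densities(img, PX, min_area_um2=0.0, max_area_um2=np.inf)
        assert len(objs) == 3


class TestPMANormalization:
    def test_percent_of_control(self):
        table, summary = sted.normalize_pma_increase(
            [10.0, 13.0], ["-PMA", "+PMA"], ["c1", "c1"]
        )
        assert table.loc[table.group == "+PMA", "percent_of_control"].iloc[0] == pytest.approx(130.0)

    def test_control_self_normalises_to_100(self, rng):
        values = rng.uniform(5, 15, 30)
        cultures = ["c1"] * 15 + ["c2"] * 15
        table, summary = sted.normalize_pma_increase(values, ["-PMA"] * 30, cultures)
        for culture in ("c1", "c2"):
            assert table.loc[table.culture == culture, "percent_of_control"].mean() == pytest.approx(100.0)

    def test_planted_uniform_effect_recovered(self, rng):
        values, groups, cultures = [], [], []
        for c in range(3):
            base = rng.uniform(5, 20)
            for _ in range(10):
                values.append(base * (1 + rng.normal(0, 0.02)))
                groups.append("-PMA")
                cultures.append(f"c{c}")
            for _ in range(10):
                values.append(1.30 * base * (1 + rng.normal(0, 0.02)))
                groups.append("+PMA")
                cultures.append(f"c{c}")
        _, summary = sted.normalize_pma_increase(values, groups, cultures)
        plus = summary.loc[summary.group == "+PMA"].iloc[0]
        assert plus["mean"] == pytest.approx(130.0, abs=3 * plus["sem"] + 0.5)

    def test_culture_without_control_rejected(self):
        with pytest.raises(ValueError, match="without"):
            sted.normalize_pma_increase([1.0, 2.0], ["+PMA", "+PMA"], ["c1", "c1"])
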