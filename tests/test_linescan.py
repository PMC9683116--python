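"""Linescan extraction, furrow registration and normalization contracts."""

import numpy as np
import pytest

from ringmetrics import (
    CortexPath,
    FurrowLine,
    SimParams,
    extract_cortical_linescan,
    extract_midzone_linescan,
    make_profile_fixture,
    normalize_profile,
    preprocess_movie,
    register_to_furrow,
    simulate_division_movie,
)


def straight_path(x0=10.0, y0=10.0, length=100.0, width=5):
    return CortexPath(np.array([[x0, y0], [x0, y0 + length]]), width_px=width)


class TestExtraction:
    def test_uniform_image_gives_uniform_profile(self):
        image = np.full((128, 128), 7.0)
        profile = extract_cortical_linescan(image, straight_path())
        np.testing.assert_allclose(profile.intensity, 7.0)

    def test_width_averages_symmetrically_across_a_gradient(self):
        # Constant along y, linear in x: perpendicular samples of a vertical
        # path average to the value at the path's own column.
        image = np.tile(np.arange(128, dtype=float), (128, 1))
        profile = extract_cortical_linescan(image, straight_path(x0=30.0))
        np.testing.assert_allclose(profile.intensity, 30.0)

    def test_sample_count_is_rounded_arc_length_plus_one(self):
        image = np.zeros((128, 128))
        profile = extract_cortical_linescan(image, straight_path(length=100.0))
        assert len(profile) == 101
        line = FurrowLine(np.array([[10.0, 20.0], [110.0, 20.0]]))
        assert len(extract_midzone_linescan(image, line)) == 101

    def test_midzone_offsets_measured_from_line_midpoint(self):
        image = np.zeros((64, 64))
        line = FurrowLine(np.array([[5.0, 30.0], [55.0, 30.0]]))
        profile = extract_midzone_linescan(image, line)
        assert profile.furrow_offset_px[0] == pytest.approx(-25.0)
        assert profile.furrow_offset_px[-1] == pytest.approx(25.0)

    def test_midzone_peak_found_at_band_center(self):
        image = np.zeros((64, 128))
        image[:, 62:65] = 300.0  # band centred at x = 63
        image[:, 63] = 500.0
        line = FurrowLine(np.array([[13.0, 32.0], [113.0, 32.0]]))
        profile = extract_midzone_linescan(image, line, width_px=3)
        assert abs(profile.arc_position_px[np.argmax(profile.intensity)] - 50.0) <= 1.0

    def test_out_of_image_path_rejected(self):
        image = np.zeros((32, 32))
        path = CortexPath(np.array([[-50.0, -50.0], [-50.0, 0.0]]))
        with pytest.raises(ValueError, match="outside"):
            extract_cortical_linescan(image, path)

    def test_simulated_peak_lands_at_truth_equator(self, noiseless_sim):
        movie, truth = noiseless_sim
        _, plane = preprocess_movie(movie)
        t = truth.params.ingression_start_frame
        profile = extract_cortical_linescan(
            plane, CortexPath(truth.cortex_path[t], frame_index=t)
        )
        # The equator is the arc midpoint of the pole-to-pole path.
        expected = profile.arc_position_px[-1] / 2.0
        peak_arc = profile.arc_position_px[np.argmax(profile.intensity)]
        assert abs(peak_arc - expected) <= 2.0


class TestRegisterToFurrow:
    def test_crossing_sample_has_zero_offset(self):
        image = np.zeros((200, 200))
        path = straight_path(x0=50.0, y0=20.0, length=160.0)
        profile = extract_cortical_linescan(image, path)
        furrow = FurrowLine(np.array([[40.0, 140.0], [60.0, 140.0]]))
        registered = register_to_furrow(profile, furrow)
        crossing = np.argmin(np.abs(registered.furrow_offset_px))
        assert registered.furrow_offset_px[crossing] == pytest.approx(0.0, abs=1e-9)
        assert registered.arc_position_px[crossing] == pytest.approx(120.0)

    def test_offsets_strictly_increase_with_arc_position(self):
        image = np.zeros((200, 200))
        profile = extract_cortical_linescan(image, straight_path(length=150.0))
        registered = register_to_furrow(
            profile, FurrowLine(np.array([[0.0, 80.0], [20.0, 80.0]]))
        )
        assert np.all(np.diff(registered.furrow_offset_px) > 0)

    def test_distant_furrow_rejected(self):
        image = np.zeros((200, 200))
        profile = extract_cortical_linescan(image, straight_path())
        far = FurrowLine(np.array([[150.0, 50.0], [160.0, 50.0]]))
        with pytest.raises(ValueError, match="farther"):
            register_to_furrow(profile, far)

    def test_simulated_zero_offset_matches_truth_furrow(self, noiseless_sim):
        movie, truth = noiseless_sim
        _, plane = preprocess_movie(movie)
        t = truth.params.ingression_start_frame
        profile = extract_cortical_linescan(
            plane, CortexPath(truth.cortex_path[t], frame_index=t)
        )
        registered = register_to_furrow(
            profile, FurrowLine(truth.furrow_line[t], frame_index=t)
        )
        crossing = np.argmin(np.abs(registered.furrow_offset_px))
        expected = profile.arc_position_px[-1] / 2.0  # equator arc position
        assert abs(registered.arc_position_px[crossing] - expected) <= 2.0


class TestNormalize:
    def test_baseline_and_peak_height(self):
        profile = make_profile_fixture(301, baseline=100.0, peak_height=200.0,
                                       peak_center=150, peak_sigma=8.0)
        norm = normalize_profile(profile)
        assert norm.baseline == pytest.approx(100.0, rel=1e-6)
        assert norm.peak_height == pytest.approx(200.0, rel=1e-4)
        assert norm.peak_index == 150

    def test_flat_profile_has_zero_peak_height(self):
        profile = make_profile_fixture(301, 100.0, 0.0, 150, 8.0)
        norm = normalize_profile(profile)
        assert norm.peak_height == 0.0

    def test_gaussian_fixture_recovers_height_within_one_percent(self):
        profile = make_profile_fixture(301, 50.0, 450.0, 150, peak_sigma=10.0)
        norm = normalize_profile(profile)  # windows end 10 sigma from the peak
        assert norm.peak_height == pytest.approx(450.0, rel=0.01)

    def test_min_window_convention_and_both_option(self):
        intensity = np.concatenate([np.full(50, 80.0), np.zeros(100), np.full(50, 120.0)])
        intensity[100] = 500.0
        profile = make_profile_fixture(200, 0.0, 0.0, 100, 1.0)
        profile.intensity = intensity
        assert normalize_profile(profile, "min").baseline == pytest.approx(80.0)
        assert normalize_profile(profile, "both").baseline == pytest.approx(100.0)

    def test_profile_shorter_than_two_pole_windows_rejected(self):
        with pytest.warns(UserWarning):  # peak unavoidably inside a window
            profile = make_profile_fixture(120, 0.0, 10.0, 60, 5.0, pole_window_px=70)
        with pytest.raises(ValueError, match="pole window"):
            normalize_profile(profile)

    def test_additive_offset_moves_baseline_not_height(self):
        profile = make_profile_fixture(301, 100.0, 200.0, 150, 8.0)
        shifted = make_profile_fixture(301, 100.0 + 37.0, 200.0, 150, 8.0)
        a, b = normalize_profile(profile), normalize_profile(shifted)
        assert b.baseline - a.baseline == pytest.approx(37.0, abs=1e-9)
        assert b.peak_height == pytest.approx(a.peak_height, abs=1e-9)

    def test_multiplicative_scaling_scales_height(self):
        profile = make_profile_fixture(301, 100.0, 200.0, 150, 8.0)
        scaled = make_profile_fixture(301, 250.0, 500.0, 150, 8.0)  # x2.5
        a, b = normalize_profile(profile), normalize_profile(scaled)
        assert b.peak_height == pytest.approx(2.5 * a.peak_height, rel=1e-9)

    def test_reversal_flips_profile_and_offsets(self):
        image = np.zeros((200, 200))
        image[60, :] = 300.0
        path = straight_path(x0=50.0, y0=20.0, length=160.0)
        profile = register_to_furrow(
            extract_cortical_linescan(image, path),
            FurrowLine(np.array([[40.0, 60.0], [60.0, 60.0]])),
        )
        rev = register_to_furrow(
            extract_cortical_linescan(image, path.reversed()),
            FurrowLine(np.array([[40.0, 60.0], [60.0, 60.0]])),
        )
        np.testing.assert_allclose(rev.intensity, profile.intensity[::-1], atol=1e-9)
        np.testing.assert_allclose(
            rev.furrow_offset_px, -profile.furrow_offset_px[::-1], atol=1e-6
        )
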