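"""Breadth, enrichment, ingression-duration and group-summary contracts."""

import numpy as np
import pandas as pd
import pytest

from ringmetrics import (
    QuantConfig,
    SimParams,
    breadth_fraction,
    cortex_cytosol_ratio,
    furrow_enrichment,
    ingression_duration,
    make_profile_fixture,
    normalize_profile,
    peak_breadth,
    summarize_groups,
)
from ringmetrics.simulate import gaussian_band_width
from ringmetrics.validation import measure_metaphase_ratio, measure_simulated_cell


def brute_force_breadth(intensity, baseline, peak_height, peak_index, fraction):
    """Independent oracle: enumerate all samples above the cutoff, take the
    contiguous run containing the peak."""
    cutoff = baseline + fraction * peak_height
    above = [i for i, v in enumerate(intensity) if v >= cutoff]
    run = {peak_index}
    changed = True
    while changed:
        changed = False
        for i in above:
            if i not in run and (i + 1 in run or i - 1 in run):
                run.add(i)
                changed = True
    return len(run), len(above) - len(run)


def rect_profile(n=200, peak_start=95, peak_len=10, height=200.0, baseline=0.0,
                 pixel_size=0.133):
    intensity = np.full(n, baseline)
    intensity[peak_start : peak_start + peak_len] = baseline + height
    profile = make_profile_fixture(n, baseline, 0.0, peak_start + peak_len // 2, 1.0,
                                   pixel_size_um=pixel_size)
    profile.intensity = intensity
    return normalize_profile(profile)


class TestPeakBreadth:
    def test_rectangular_peak_counts_and_converts(self, config):
        profile = rect_profile()
        result = peak_breadth(profile, config)
        assert result.breadth_px == 10
        assert result.breadth_um == pytest.approx(1.33)

    def test_isolated_spike_excluded_from_breadth(self, config):
        profile = rect_profile()
        profile.intensity[190] = 200.0  # off-peak sample above the cutoff
        profile = normalize_profile(profile)
        result = peak_breadth(profile, config)
        assert result.breadth_px == 10
        assert result.excluded_pixel_count == 1

    def test_gaussian_width_matches_analytic_fwhm(self, config):
        profile = normalize_profile(
            make_profile_fixture(301, 0.0, 500.0, 150, peak_sigma=8.0)
        )
        result = peak_breadth(profile, config)
        assert abs(result.breadth_px - 2 * 8.0 * np.sqrt(2 * np.log(2))) <= 1.0

    def test_agrees_with_brute_force_on_random_profiles(self, config, rng):
        for _ in range(200):
            n = int(rng.integers(120, 400))
            profile = make_profile_fixture(
                n,
                baseline=float(rng.uniform(0, 200)),
                peak_height=float(rng.uniform(50, 1000)),
                peak_center=int(rng.integers(55, n - 55)),
                peak_sigma=float(rng.uniform(2, 20)),
            )
            profile.intensity += rng.normal(0, 5.0, size=n)
            for idx in rng.integers(0, n, size=rng.integers(0, 3)):
                profile.intensity[idx] = rng.uniform(500, 2000)
            profile = normalize_profile(profile)
            if profile.peak_height <= 0:
                continue
            result = peak_breadth(profile, config)
            expected_len, expected_excl = brute_force_breadth(
                profile.intensity, profile.baseline, profile.peak_height,
                profile.peak_index, config.breadth_cutoff_fraction,
            )
            assert result.breadth_px == expected_len
            assert result.excluded_pixel_count == expected_excl

    def test_invariant_under_affine_intensity_transform(self, config):
        base = make_profile_fixture(301, 40.0, 300.0, 150, 9.0)
        for a, b in [(2.0, 0.0), (1.0, 55.0), (3.7, -20.0)]:
            transformed = make_profile_fixture(301, 40.0, 300.0, 150, 9.0)
            transformed.intensity = a * base.intensity + b
            r0 = peak_breadth(normalize_profile(base), config)
            r1 = peak_breadth(normalize_profile(transformed), config)
            assert r1.breadth_px == r0.breadth_px
            assert r1.peak_region == r0.peak_region

    def test_flat_profile_rejected(self, config):
        profile = normalize_profile(make_profile_fixture(301, 100.0, 0.0, 150, 8.0))
        with pytest.raises(ValueError, match="peak"):
            peak_breadth(profile, config)

    def test_breadth_increases_with_band_sigma(self):
        # Monotonicity of the measured breadth in the generative band width.
        widths = []
        for sigma in (1.5, 2.0, 2.5):
            params = SimParams(noise_model="none", enrichment_sigma_um=sigma)
            widths.append(measure_simulated_cell(params)["breadth_um"])
        assert widths[0] < widths[1] < widths[2]


class TestBreadthFraction:
    def test_simple_ratio(self, config):
        result = peak_breadth(rect_profile(), config)
        assert breadth_fraction(result, 200) == pytest.approx(0.05)

    def test_full_breadth_gives_one(self, config):
        result = peak_breadth(rect_profile(), config)
        assert breadth_fraction(result, result.breadth_px) == 1.0

    def test_zero_total_rejected(self, config):
        result = peak_breadth(rect_profile(), config)
        with pytest.raises(ValueError):
            breadth_fraction(result, 0)

    def test_fraction_controls_for_cell_size(self):
        # Same band sigma in two cell sizes: absolute breadth is unchanged
        # while the fraction scales inversely with cortical length.
        small = SimParams(noise_model="none", cell_radius_um=10.0)
        big = SimParams(noise_model="none", cell_radius_um=13.0,
                        image_shape=(180, 180))
        r_small = measure_simulated_cell(small)
        r_big = measure_simulated_cell(big)
        assert r_big["breadth_um"] == pytest.approx(r_small["breadth_um"], rel=0.15)


class TestEnrichment:
    def test_uniform_profile_gives_ratio_one(self, config):
        profile = rect_profile(height=0.0, baseline=100.0)
        profile.intensity[100] = 100.0001  # minimal peak to define a region
        profile = normalize_profile(profile)
        result = furrow_enrichment(profile, peak_breadth(profile, config), config)
        assert result.enrichment_ratio == pytest.approx(1.0, rel=1e-4)

    def test_constructed_five_fold(self, config):
        profile = rect_profile(height=400.0, baseline=100.0)
        result = furrow_enrichment(profile, peak_breadth(profile, config), config)
        assert result.furrow_mean == pytest.approx(500.0)
        assert result.pole_mean == pytest.approx(100.0)
        assert result.enrichment_ratio == pytest.approx(5.0)

    def test_scaling_invariance_but_not_offset(self, config):
        profile = rect_profile(height=400.0, baseline=100.0)
        ratio = furrow_enrichment(profile, peak_breadth(profile, config), config).enrichment_ratio

        scaled = rect_profile(height=400.0, baseline=100.0)
        scaled.intensity = scaled.intensity * 3.0
        scaled = normalize_profile(scaled)
        ratio_scaled = furrow_enrichment(scaled, peak_breadth(scaled, config), config).enrichment_ratio
        assert ratio_scaled == pytest.approx(ratio, rel=1e-9)

        offset = rect_profile(height=400.0, baseline=100.0)
        offset.intensity = offset.intensity + 200.0
        offset = normalize_profile(offset)
        ratio_offset = furrow_enrichment(offset, peak_breadth(offset, config), config).enrichment_ratio
        assert ratio_offset != pytest.approx(ratio, rel=0.05)

    def test_zero_pole_mean_rejected(self, config):
        profile = rect_profile(height=400.0, baseline=0.0)
        with pytest.raises(ValueError, match="pole"):
            furrow_enrichment(profile, peak_breadth(profile, config), config)

    def test_reversal_leaves_breadth_and_enrichment_unchanged(self, config):
        profile = normalize_profile(make_profile_fixture(301, 80.0, 400.0, 140, 9.0))
        rev = normalize_profile(profile.reversed())
        b, b_rev = peak_breadth(profile, config), peak_breadth(rev, config)
        assert b_rev.breadth_px == b.breadth_px
        e = furrow_enrichment(profile, b, config).enrichment_ratio
        e_rev = furrow_enrichment(rev, b_rev, config).enrichment_ratio
        assert e_rev == pytest.approx(e, rel=1e-9)


class TestCortexCytosol:
    def test_equal_means_give_one(self):
        profile = make_profile_fixture(200, 100.0, 0.0, 100, 1.0)
        assert cortex_cytosol_ratio(profile, 100.0).cortex_cytosol_ratio == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        profile = make_profile_fixture(200, 160.0, 0.0, 100, 1.0)
        assert cortex_cytosol_ratio(profile, 100.0).cortex_cytosol_ratio == pytest.approx(1.6)

    def test_zero_cytosol_rejected(self):
        profile = make_profile_fixture(200, 160.0, 0.0, 100, 1.0)
        with pytest.raises(ValueError):
            cortex_cytosol_ratio(profile, 0.0)

    def test_simulated_metaphase_ratio_recovered(self):
        params = SimParams(noise_model="none", cortex_level=120.0,
                           cytosol_level=200.0, seed=2)
        result = measure_metaphase_ratio(params)
        assert result["true_cortex_cytosol_ratio"] == pytest.approx(0.6)
        assert result["cortex_cytosol_ratio"] == pytest.approx(0.6, rel=0.10)


class TestIngressionDuration:
    def test_duration_arithmetic(self, config):
        trace = np.concatenate([np.linspace(100, 2, 10), [0.5, 0.5]])
        result = ingression_duration(trace, 0, 2.0, config)
        assert result.closed and result.closure_frame == 10
        assert result.duration_min == 20.0

    def test_never_closing_trace_flagged(self, config):
        result = ingression_duration(np.linspace(100, 10, 20), 0, 2.0, config)
        assert not result.closed
        assert result.duration_min is None and result.closure_frame is None

    def test_simulated_duration_within_one_interval(self, realistic_sim):
        params, (_, truth) = realistic_sim
        result = ingression_duration(
            truth.furrow_width_trace_px(), truth.anaphase_frame,
            params.frame_interval_min, QuantConfig(),
        )
        assert abs(result.duration_min - truth.true_ingression_duration_min) \
            <= params.frame_interval_min

    def test_bad_anaphase_frame_rejected(self, config):
        with pytest.raises(ValueError):
            ingression_duration(np.ones(5), 7, 1.0, config)


class TestSummarizeGroups:
    def test_single_value_flagged(self):
        df = pd.DataFrame({"cell_line": ["HeLa"], "value": [5.0]})
        out = summarize_groups(df)
        row = out.iloc[0]
        assert row["n"] == 1 and row["mean"] == 5.0 and row["sd"] == 0.0
        assert bool(row["single_observation"])

    def test_two_values(self):
        df = pd.DataFrame({"cell_line": ["a", "a"], "value": [1.0, 3.0]})
        row = summarize_groups(df).iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(np.sqrt(2.0))

    def test_monte_carlo_matches_generative_moments(self, rng):
        values = rng.normal(20.0, 2.0, size=100)
        df = pd.DataFrame({"cell_line": ["x"] * 100, "value": values})
        row = summarize_groups(df).iloc[0]
        assert row["mean"] == pytest.approx(20.0, abs=3 * 2.0 / 10)
        assert row["sd"] == pytest.approx(2.0, rel=0.35)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_groups(pd.DataFrame({"cell_line": [], "value": []}))


def test_band_width_helper_matches_fwhm_formula():
    assert gaussian_band_width(2.0, 0.5) == pytest.approx(2 * 2.0 * np.sqrt(2 * np.log(2)))
    with pytest.raises(ValueError):
        gaussian_band_width(2.0, 1.5)
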