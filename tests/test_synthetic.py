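"""Synthetic landscape generator: determinism, succession physics,
mixture rendering, plots, albedo and kernels."""

import numpy as np
import pytest
from shapely.geometry import Point

from borealshift import synthetic as syn
from borealshift.synthetic import (
    BANDS,
    DEFAULT_ENDMEMBERS,
    SEASONS,
    ConfigurationError,
    GenerationConfig,
    generate_truth,
    evaluate_composition,
    mixture_reflectance,
    render_albedo,
    render_kernel,
    render_reflectance,
    sample_plots,
)


def uniform_truth(dec=0.5, cover=0.5, shape=(8, 8), **kw) -> syn.LandscapeTruth:
    """Truth with spatially constant composition and no fires."""
    cfg = GenerationConfig(
        grid_shape=shape,
        n_fires=0,
        dec_base_mean=dec,
        dec_base_sd=0.0,
        cover_base_mean=cover,
        cover_base_sd=0.0,
        **kw,
    )
    return generate_truth(cfg, seed=3)


class TestGenerateTruth:
    def test_identical_seed_gives_byte_identical_truth(self):
        a = generate_truth(GenerationConfig(grid_shape=(32, 32)), seed=1)
        b = generate_truth(GenerationConfig(grid_shape=(32, 32)), seed=1)
        np.testing.assert_array_equal(a.dec_base, b.dec_base)
        np.testing.assert_array_equal(a.cover_base, b.cover_base)
        np.testing.assert_array_equal(a.dem, b.dem)
        assert len(a.fires) == len(b.fires)
        for fa, fb in zip(a.fires, b.fires):
            assert fa.year == fb.year and fa.polygon.equals(fb.polygon)

    def test_different_seed_changes_fields(self):
        a = generate_truth(GenerationConfig(grid_shape=(32, 32)), seed=1)
        b = generate_truth(GenerationConfig(grid_shape=(32, 32)), seed=2)
        assert not np.array_equal(a.dec_base, b.dec_base)

    def test_fraction_fields_within_unit_interval(self, small_truth):
        for year in (1950, 1980, 2000, 2015):
            dec, cover = evaluate_composition(small_truth, year)
            assert dec.min() >= 0 and dec.max() <= 1
            assert cover.min() >= 0 and cover.max() <= 1

    def test_zero_fires_means_static_composition(self):
        truth = uniform_truth()
        for year in (1960, 2000, 2015):
            dec, cover = evaluate_composition(truth, year)
            np.testing.assert_array_equal(dec, truth.dec_base)
            np.testing.assert_array_equal(cover, truth.cover_base)

    def test_fire_years_within_range(self, small_truth):
        assert all(1950 <= f.year <= 2018 for f in small_truth.fires)

    def test_burned_fraction_matches_pointwise_polygon_scan(self, small_truth):
        """Vectorized rasterization agrees with a per-pixel point-in-polygon
        loop (independent scalar code path)."""
        years = syn.most_recent_fire_year(small_truth.fires, small_truth.grid_shape)
        burned_frac = (years >= 0).mean()
        rows, cols = small_truth.grid_shape
        count = 0
        for r in range(rows):
            for c in range(cols):
                p = Point(c + 0.5, r + 0.5)
                if any(f.polygon.covers(p) for f in small_truth.fires):
                    count += 1
        assert burned_frac == count / (rows * cols)

    @pytest.mark.parametrize(
        "bad",
        [
            {"d_late": 0.8, "d_peak": 0.5},
            {"grid_shape": (0, 10)},
            {"tau_d": -1.0},
            {"fire_year_range": (1900, 2018)},
        ],
    )
    def test_invalid_config_raises_naming_field(self, bad):
        with pytest.raises(ConfigurationError):
            generate_truth(GenerationConfig(**bad), seed=0)


class TestSuccession:
    def test_deciduous_pulse_peaks_at_tau_d(self, small_truth):
        p = small_truth.succession_params
        dec, _ = syn.succession_curves(p, np.array([p["tau_d"]]))
        assert dec[0] == pytest.approx(p["d_peak"], abs=1e-12)

    def test_deciduous_relaxes_to_late_state(self, small_truth):
        p = small_truth.succession_params
        dec, _ = syn.succession_curves(p, np.array([50.0 * p["tau_d"]]))
        assert dec[0] == pytest.approx(p["d_late"], abs=1e-6)

    def test_cover_zero_in_fire_year(self, small_truth):
        p = small_truth.succession_params
        _, scale = syn.succession_curves(p, np.array([0.0]))
        assert scale[0] == 0.0

    def test_chronosequence_pattern_recent_up_old_down(self):
        """Recent burns gain deciduous fraction 2000->2015; old burns lose it."""
        truth = generate_truth(GenerationConfig(), seed=1)
        d0, _ = evaluate_composition(truth, 2000)
        d1, _ = evaluate_composition(truth, 2015)
        years = syn.most_recent_fire_year(truth.fires, truth.grid_shape)
        recent = (years >= 1999) & (years <= 2014)
        old = (years >= 1950) & (years <= 1978)
        assert recent.any() and old.any()
        assert (d1 - d0)[recent].mean() > 0
        assert (d1 - d0)[old].mean() <= 0


class TestRenderReflectance:
    def test_pure_deciduous_closed_canopy_returns_endmember(self):
        truth = uniform_truth(dec=1.0, cover=1.0)
        for season in SEASONS:
            stack = render_reflectance(truth, 2000, season, n_dates=2,
                                       cloud_fraction=0.0, noise_sd=0.0)
            s = SEASONS.index(season)
            for i, band in enumerate(BANDS):
                np.testing.assert_array_equal(
                    stack.bands[:, i], DEFAULT_ENDMEMBERS[0, s, i]
                )
            assert stack.valid.all()

    def test_zero_cover_is_background_regardless_of_composition(self):
        for dec in (0.0, 0.4, 1.0):
            truth = uniform_truth(dec=dec, cover=0.0)
            stack = render_reflectance(truth, 2000, "summer", n_dates=1,
                                       cloud_fraction=0.0, noise_sd=0.0)
            for i in range(6):
                np.testing.assert_array_equal(
                    stack.bands[0, i], DEFAULT_ENDMEMBERS[2, 1, i]
                )

    def test_half_mixture_matches_hand_arithmetic(self):
        truth = uniform_truth(dec=0.5, cover=0.5)
        stack = render_reflectance(truth, 2000, "summer", n_dates=1,
                                   cloud_fraction=0.0, noise_sd=0.0)
        e = DEFAULT_ENDMEMBERS
        for i in range(6):
            expected = 0.5 * (0.5 * e[0, 1, i] + 0.5 * e[1, 1, i]) + 0.5 * e[2, 1, i]
            np.testing.assert_allclose(stack.bands[0, i], expected, atol=1e-15)

    def test_summer_nir_contrast_exceeds_spring(self):
        e = DEFAULT_ENDMEMBERS
        nir = BANDS.index("nir")
        summer_contrast = e[0, 1, nir] - e[1, 1, nir]
        spring_contrast = e[0, 0, nir] - e[1, 0, nir]
        assert summer_contrast > spring_contrast > 0

    def test_mixture_linear_in_composition(self, rng):
        """With zero noise, reflectance is exactly linear in d and in c."""
        shape = (4, 4)
        for _ in range(10):
            d1, d2, c = rng.uniform(0, 1, 3)
            mid = mixture_reflectance(
                DEFAULT_ENDMEMBERS, "fall",
                np.full(shape, (d1 + d2) / 2), np.full(shape, c),
            )
            ends = [
                mixture_reflectance(DEFAULT_ENDMEMBERS, "fall", np.full(shape, d), np.full(shape, c))
                for d in (d1, d2)
            ]
            np.testing.assert_allclose(mid, (ends[0] + ends[1]) / 2, atol=1e-12)
            c1, c2, d = rng.uniform(0, 1, 3)
            mid = mixture_reflectance(
                DEFAULT_ENDMEMBERS, "fall",
                np.full(shape, d), np.full(shape, (c1 + c2) / 2),
            )
            ends = [
                mixture_reflectance(DEFAULT_ENDMEMBERS, "fall", np.full(shape, d), np.full(shape, c))
                for c in (c1, c2)
            ]
            np.testing.assert_allclose(mid, (ends[0] + ends[1]) / 2, atol=1e-12)

    def test_unknown_season_rejected(self, small_truth):
        with pytest.raises(ValueError, match="season"):
            render_reflectance(small_truth, 2000, "winter")


class TestSamplePlots:
    def test_noiseless_share_equals_pixel_dec(self, small_truth):
        plots = sample_plots(small_truth, 2000, 50, ba_noise=0.0, seed=1)
        dec, _ = evaluate_composition(small_truth, 2000)
        share = plots.deciduous_ba / (plots.deciduous_ba + plots.evergreen_ba)
        np.testing.assert_allclose(
            share, dec[plots.row, plots.col], atol=1e-12
        )

    def test_fixed_seed_reproduces_table(self, small_truth):
        a = sample_plots(small_truth, 2000, 100, seed=4)
        b = sample_plots(small_truth, 2000, 100, seed=4)
        assert a.equals(b)

    def test_aggregated_share_matches_pixel_mean(self, small_truth):
        """Over many noiseless plots the mean plot share equals the mean
        deciduous fraction of the sampled pixels."""
        plots = sample_plots(small_truth, 2000, 10_000, ba_noise=0.0, seed=2)
        dec, _ = evaluate_composition(small_truth, 2000)
        share = plots.deciduous_ba / (plots.deciduous_ba + plots.evergreen_ba)
        assert abs(share.mean() - dec[plots.row, plots.col].mean()) < 1e-12

    def test_plots_only_on_covered_pixels(self, small_truth):
        plots = sample_plots(small_truth, 2000, 200, seed=0)
        _, cover = evaluate_composition(small_truth, 2000)
        assert (cover[plots.row, plots.col] > 0).all()

    def test_no_eligible_pixels_is_error(self):
        truth = uniform_truth(cover=0.0)
        with pytest.raises(ValueError, match="eligible"):
            sample_plots(truth, 2000, 10)


class TestRenderAlbedo:
    def test_uniform_composition_gives_closed_form_everywhere(self):
        truth = uniform_truth(dec=0.3, cover=0.6, shape=(8, 8))
        for season in SEASONS:
            ca = render_albedo(truth, 2000, season, coarse_factor=4, noise_sd=0.0)
            b = truth.albedo_coeffs[season]
            expected = b["b0"] + b["b_d"] * 0.3 + b["b_c"] * 0.6 + b["b_dc"] * 0.18
            np.testing.assert_allclose(ca.values, expected, atol=1e-12)

    def test_block_average_of_crafted_quartet(self):
        truth = uniform_truth(shape=(2, 2))
        truth.dec_base = np.array([[0.3, 0.4], [0.5, 0.6]])
        truth.cover_base = np.zeros((2, 2))
        truth.albedo_coeffs = {"summer": {"b0": 0.0, "b_d": 1.0, "b_c": 0.0, "b_dc": 0.0}}
        ca = render_albedo(truth, 2000, "summer", coarse_factor=2, noise_sd=0.0)
        assert ca.values.shape == (1, 1)
        assert ca.values[0, 0] == pytest.approx(0.45, abs=1e-12)

    def test_spring_albedo_decreases_with_canopy(self):
        b = syn.DEFAULT_ALBEDO_COEFFS["spring"]
        c = np.linspace(0, 1, 11)
        for d in (0.0, 0.5, 1.0):
            alpha = syn.composition_albedo(b, np.full_like(c, d), c)
            assert np.all(np.diff(alpha) < 0)

    def test_albedo_increases_with_deciduous_every_season(self):
        d = np.linspace(0, 1, 11)
        for season, b in syn.DEFAULT_ALBEDO_COEFFS.items():
            for c in (0.0, 0.5, 1.0):
                alpha = syn.composition_albedo(b, d, np.full_like(d, c))
                assert np.all(np.diff(alpha) > 0), season

    def test_non_divisible_factor_rejected(self, small_truth):
        with pytest.raises(ValueError, match="divide"):
            render_albedo(small_truth, 2000, "spring", coarse_factor=7)


class TestRenderKernel:
    def test_kernels_negative_everywhere(self, small_truth):
        for season in SEASONS:
            k = render_kernel(small_truth, season, coarse_factor=4)
            assert (k < 0).all()

    def test_constant_configuration(self):
        truth = uniform_truth(shape=(8, 8), kernel_rel_sd=0.0)
        k = render_kernel(truth, "summer", coarse_factor=4)
        np.testing.assert_array_equal(k, -150.0)

    def test_smooth_kernel_mean_near_configured(self, small_truth):
        for season, mean in syn.DEFAULT_KERNEL_MEANS.items():
            k = render_kernel(small_truth, season, coarse_factor=4)
            assert abs(k.mean() - mean) < 0.05 * abs(mean)
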