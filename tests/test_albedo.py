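"""Albedo compositing, bicubic downscaling, albedo modelling and forcing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from borealshift import albedo as alb
from borealshift import synthetic as syn
from borealshift.cover_mapping import CoverMap, SOURCE_THREE_SEASON


def make_cover_map(values, response="deciduous_fraction", epoch=2000):
    values = np.asarray(values, dtype=float)
    source = np.where(np.isfinite(values), SOURCE_THREE_SEASON, 0).astype(np.uint8)
    return CoverMap(
        response=response,
        epoch=epoch,
        estimate=values,
        uncertainty=np.zeros_like(values),
        source_mode=source,
    )


class TestSeasonalComposite:
    def test_even_count_mean_of_middles(self):
        days = np.array([[[0.2]], [[0.6]]])
        out = alb.seasonal_albedo_composite(days, np.ones((2, 1, 1), bool), "spring")
        assert out.albedo[0, 0] == pytest.approx(0.4)

    def test_single_valid_day_passthrough(self):
        days = np.array([[[0.3]], [[0.9]]])
        valid = np.array([[[True]], [[False]]])
        out = alb.seasonal_albedo_composite(days, valid, "fall")
        assert out.albedo[0, 0] == 0.3

    def test_all_days_invalid_masked(self):
        days = np.zeros((3, 2, 2))
        out = alb.seasonal_albedo_composite(days, np.zeros((3, 2, 2), bool), "summer")
        assert not out.valid_mask.any()
        assert np.isnan(out.albedo).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            alb.seasonal_albedo_composite(np.zeros((2, 3, 3)), np.ones((2, 4, 4), bool), "spring")


def naive_keys_bicubic(coarse, factor, a=-0.5):
    """Independent scalar-loop bicubic convolution oracle (clamped edges)."""

    def kernel(x):
        x = abs(x)
        if x <= 1:
            return (a + 2) * x**3 - (a + 3) * x**2 + 1
        if x < 2:
            return a * x**3 - 5 * a * x**2 + 8 * a * x - 4 * a
        return 0.0

    nr, nc = coarse.shape
    out = np.zeros((nr * factor, nc * factor))
    for i in range(nr * factor):
        u = (i + 0.5) / factor - 0.5
        bi = int(np.floor(u))
        for j in range(nc * factor):
            v = (j + 0.5) / factor - 0.5
            bj = int(np.floor(v))
            acc = 0.0
            for ti in range(-1, 3):
                wi = kernel(u - (bi + ti))
                ri = min(max(bi + ti, 0), nr - 1)
                for tj in range(-1, 3):
                    wj = kernel(v - (bj + tj))
                    cj = min(max(bj + tj, 0), nc - 1)
                    acc += wi * wj * coarse[ri, cj]
            out[i, j] = acc
    return out


class TestDownscale:
    def test_constant_preserved(self):
        out = alb.downscale(np.full((4, 4), 0.37), 4)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_linear_ramp_preserved_away_from_edges(self):
        coarse = np.outer(np.ones(6), np.arange(6, dtype=float))
        out = alb.downscale(coarse, 4)
        # interior fine columns follow the same linear ramp in coarse coords
        j = np.arange(out.shape[1])
        expected = (j + 0.5) / 4 - 0.5
        interior = slice(8, -8)
        np.testing.assert_allclose(out[10, interior], expected[interior], atol=1e-6)

    def test_single_bright_cell_matches_scalar_oracle(self, rng):
        coarse = np.zeros((5, 5))
        coarse[2, 3] = 1.0
        out = alb.downscale(coarse, 3)
        np.testing.assert_allclose(out, naive_keys_bicubic(coarse, 3), atol=1e-10)

    def test_random_field_matches_scalar_oracle(self, rng):
        coarse = rng.uniform(0, 1, (4, 6))
        out = alb.downscale(coarse, 2)
        np.testing.assert_allclose(out, naive_keys_bicubic(coarse, 2), atol=1e-10)

    def test_clip_range_applied(self):
        coarse = np.zeros((4, 4))
        coarse[1, 1] = 1.0  # cubic overshoot goes negative nearby
        out = alb.downscale(coarse, 4, clip_range=(0.0, 1.0))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_fractional_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            alb.downscale(np.zeros((4, 4)), 0.5)


class TestAlbedoTraining:
    def test_uniform_albedo_occupies_all_bins(self, rng):
        vals = rng.uniform(0, 1, (40, 40))
        sa = alb.SeasonalAlbedo("spring", 2000, vals, np.ones_like(vals, bool))
        d = make_cover_map(rng.uniform(0, 1, (40, 40)))
        c = make_cover_map(rng.uniform(0, 1, (40, 40)), "tree_canopy_cover")
        rec = alb.sample_albedo_training(sa, d, c, n_per_bin=20, seed=0)
        bins = np.clip((rec["albedo"] * 10).astype(int), 0, 9)
        hist, _ = np.histogram(vals, bins=10, range=(0, 1))  # oracle premise
        assert (hist > 0).all()
        assert set(bins) == set(range(10))
        assert len(rec) <= 200

    def test_fixed_seed_identical_records(self, rng):
        vals = rng.uniform(0, 1, (20, 20))
        sa = alb.SeasonalAlbedo("fall", 2000, vals, np.ones_like(vals, bool))
        d = make_cover_map(rng.uniform(0, 1, (20, 20)))
        c = make_cover_map(rng.uniform(0, 1, (20, 20)), "tree_canopy_cover")
        a = alb.sample_albedo_training(sa, d, c, n_per_bin=10, seed=3)
        b = alb.sample_albedo_training(sa, d, c, n_per_bin=10, seed=3)
        assert a.equals(b)


def albedo_records(rng, coeffs, n=600, noise=0.0):
    import pandas as pd

    d = rng.uniform(0, 1, n)
    c = rng.uniform(0, 1, n)
    a = syn.composition_albedo(coeffs, d, c) + rng.normal(0, noise, n)
    return pd.DataFrame(
        {"deciduous_fraction": d, "tree_canopy_cover": c, "albedo": a}
    )


class TestAlbedoModel:
    def test_deciduous_only_truth_gives_deciduous_importance(self, rng):
        rec = albedo_records(rng, {"b0": 0.2, "b_d": 0.3, "b_c": 0.0, "b_dc": 0.0})
        _, imp, _ = alb.fit_albedo_model(rec, seed=0)
        assert imp["deciduous_fraction"] > 0.9

    def test_spring_truth_canopy_dominates(self, rng):
        rec = albedo_records(rng, syn.DEFAULT_ALBEDO_COEFFS["spring"])
        _, imp, _ = alb.fit_albedo_model(rec, seed=0)
        assert imp["tree_canopy_cover"] > imp["deciduous_fraction"]

    def test_summer_truth_deciduous_dominates(self, rng):
        rec = albedo_records(rng, syn.DEFAULT_ALBEDO_COEFFS["summer"])
        _, imp, _ = alb.fit_albedo_model(rec, seed=0)
        assert imp["deciduous_fraction"] > imp["tree_canopy_cover"]

    def test_zero_noise_cv_r2_high(self, rng):
        rec = albedo_records(rng, syn.DEFAULT_ALBEDO_COEFFS["spring"])
        _, _, cv_r2 = alb.fit_albedo_model(rec, seed=0)
        assert cv_r2 >= 0.95

    def test_constant_predictor_rejected(self, rng):
        rec = albedo_records(rng, syn.DEFAULT_ALBEDO_COEFFS["fall"])
        rec["tree_canopy_cover"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            alb.fit_albedo_model(rec, seed=0)

    def test_too_few_records_rejected(self, rng):
        rec = albedo_records(rng, syn.DEFAULT_ALBEDO_COEFFS["fall"], n=20)
        with pytest.raises(ValueError, match="50"):
            alb.fit_albedo_model(rec, seed=0)


class TestPredictAlbedo:
    def fitted(self, rng):
        rec = albedo_records(rng, syn.DEFAULT_ALBEDO_COEFFS["spring"], noise=0.01)
        model, _, _ = alb.fit_albedo_model(rec, seed=1)
        return model, rec

    def test_identical_cover_maps_identical_predictions(self, rng):
        model, _ = self.fitted(rng)
        d = make_cover_map(rng.uniform(0, 1, (8, 8)))
        c = make_cover_map(rng.uniform(0, 1, (8, 8)), "tree_canopy_cover")
        a = alb.predict_albedo(model, d, c, "spring")
        b = alb.predict_albedo(model, d, c, "spring")
        np.testing.assert_array_equal(a.albedo, b.albedo)

    def test_predictions_within_training_range(self, rng):
        model, rec = self.fitted(rng)
        d = make_cover_map(rng.uniform(0, 1, (8, 8)))
        c = make_cover_map(rng.uniform(0, 1, (8, 8)), "tree_canopy_cover")
        out = alb.predict_albedo(model, d, c, "spring")
        assert out.albedo.min() >= rec["albedo"].min() - 1e-12
        assert out.albedo.max() <= rec["albedo"].max() + 1e-12

    def test_masked_input_masked_output(self, rng):
        model, _ = self.fitted(rng)
        vals = rng.uniform(0, 1, (6, 6))
        vals[0, 0] = np.nan
        d = make_cover_map(vals)
        c = make_cover_map(rng.uniform(0, 1, (6, 6)), "tree_canopy_cover")
        out = alb.predict_albedo(model, d, c, "spring")
        assert not out.valid_mask[0, 0]
        assert np.isnan(out.albedo[0, 0])


class TestRadiativeForcing:
    def sa(self, values, season="spring", epoch=2000):
        values = np.asarray(values, dtype=float)
        return alb.SeasonalAlbedo(season, epoch, values, np.isfinite(values))

    def test_zero_change_zero_forcing(self, rng):
        a = self.sa(rng.uniform(0, 1, (5, 5)))
        k = alb.KernelField("spring", np.full((5, 5), -120.0))
        out = alb.radiative_forcing(a, self.sa(a.albedo.copy(), epoch=2015), k)
        np.testing.assert_array_equal(out.forcing, 0.0)

    def test_hand_multiplication(self):
        a = self.sa(np.full((2, 2), 0.50))
        b = self.sa(np.full((2, 2), 0.51), epoch=2015)
        k = alb.KernelField("spring", np.full((2, 2), -120.0))
        out = alb.radiative_forcing(a, b, k)
        np.testing.assert_allclose(out.forcing, -1.2, atol=1e-10)

    def test_albedo_increase_means_cooling(self, rng):
        start = rng.uniform(0.2, 0.4, (6, 6))
        a = self.sa(start)
        b = self.sa(start + rng.uniform(0.01, 0.1, (6, 6)), epoch=2015)
        k = alb.KernelField("spring", -rng.uniform(50, 200, (6, 6)))
        out = alb.radiative_forcing(a, b, k)
        assert (out.forcing < 0).all()

    def test_season_mismatch_rejected(self, rng):
        a = self.sa(rng.uniform(0, 1, (3, 3)))
        b = self.sa(rng.uniform(0, 1, (3, 3)), season="fall", epoch=2015)
        k = alb.KernelField("spring", np.full((3, 3), -100.0))
        with pytest.raises(ValueError, match="season"):
            alb.radiative_forcing(a, b, k)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        scale=st.floats(min_value=-3, max_value=3, allow_nan=False),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_bilinearity_in_change_and_kernel(self, scale, seed):
        """Forcing is linear in the albedo change and in the kernel."""
        r = np.random.default_rng(seed)
        start = r.uniform(0.2, 0.6, (4, 4))
        delta = r.uniform(-0.1, 0.1, (4, 4))
        kern = -r.uniform(50, 200, (4, 4))
        base = alb.radiative_forcing(
            self.sa(start), self.sa(start + delta, epoch=2015),
            alb.KernelField("spring", kern),
        ).forcing
        scaled_delta = alb.radiative_forcing(
            self.sa(start), self.sa(start + scale * delta, epoch=2015),
            alb.KernelField("spring", kern),
        ).forcing
        np.testing.assert_allclose(scaled_delta, scale * base, atol=1e-9)
        scaled_kernel = alb.radiative_forcing(
            self.sa(start), self.sa(start + delta, epoch=2015),
            alb.KernelField("spring", scale * kern),
        ).forcing
        np.testing.assert_allclose(scaled_kernel, scale * base, atol=1e-9)

    def test_nonwinter_mean_is_arithmetic_mean(self, rng):
        fmaps = {}
        arrs = {}
        for s in ("spring", "summer", "fall"):
            a = self.sa(rng.uniform(0.2, 0.6, (5, 5)), season=s)
            b = self.sa(a.albedo + rng.uniform(-0.05, 0.05, (5, 5)), season=s, epoch=2015)
            k = alb.KernelField(s, -rng.uniform(50, 200, (5, 5)))
            fmaps[s] = alb.radiative_forcing(a, b, k)
            arrs[s] = fmaps[s].forcing
        mean = alb.nonwinter_mean(fmaps)
        np.testing.assert_allclose(
            mean.forcing, (arrs["spring"] + arrs["summer"] + arrs["fall"]) / 3, atol=1e-12
        )
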