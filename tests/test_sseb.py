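"""SAVI, SSEB ET fraction, seasonal upscaling, yield model and blue-WF rasters."""

from datetime import date, timedelta

import numpy as np
import pytest

from aquafoot.raster import NODATA
from aquafoot.sseb import (
    AnchorPair,
    REFERENCE_YIELD_MODELS,
    compute_savi,
    et_fraction,
    eta_daily,
    fit_yield_model,
    predict_yield,
    select_anchors,
    upscale_et_lgp,
    wf_rs_blue,
)


class TestSavi:
    def test_symmetric_bands_give_zero(self):
        red = np.full((4, 4), 0.2)
        assert np.allclose(compute_savi(red, red.copy()), 0.0)

    def test_hand_value(self):
        savi = compute_savi(np.array([[0.10]]), np.array([[0.40]]))
        assert savi[0, 0] == pytest.approx(0.45)  # 0.30/1.00 * 1.5

    def test_l_zero_reduces_to_ndvi(self):
        rng = np.random.default_rng(0)
        red = rng.uniform(0.05, 0.3, (6, 6))
        nir = rng.uniform(0.2, 0.6, (6, 6))
        ndvi = (nir - red) / (nir + red)
        np.testing.assert_allclose(compute_savi(red, nir, soil_factor=0.0), ndvi)

    def test_nodata_propagates_and_empty_scene_errors(self):
        red = np.full((3, 3), 0.1)
        nir = np.full((3, 3), 0.4)
        red[1, 1] = NODATA
        out = compute_savi(red, nir)
        assert out[1, 1] == NODATA and out[0, 0] != NODATA
        with pytest.raises(ValueError, match="empty scene"):
            compute_savi(np.full((2, 2), NODATA), np.full((2, 2), NODATA))


class TestEtFraction:
    anchors = AnchorPair(t_hot_k=320.0, t_cold_k=295.0)

    def test_anchor_identities_and_midpoint(self):
        lst = np.array([[320.0, 295.0, 307.5]])
        np.testing.assert_allclose(et_fraction(lst, self.anchors), [[0.0, 1.0, 0.5]])

    def test_clipped_to_unit_interval(self):
        lst = np.array([[330.0, 290.0]])
        np.testing.assert_allclose(et_fraction(lst, self.anchors), [[0.0, 1.0]])

    def test_inverted_anchors_rejected(self):
        with pytest.raises(ValueError):
            AnchorPair(t_hot_k=295.0, t_cold_k=320.0)


class TestAnchorSelection:
    def test_recovers_generator_anchors_on_peak_scene(self, noise_free_run):
        truth = noise_free_run["truth"]
        # a scene where some field sits on its mid-season plateau (ETf = 1)
        scene = next(
            sc
            for sc in noise_free_run["scenes"]
            if any(abs(truth.etf_by_scene[f][sc.scene_id] - 1.0) < 1e-12
                   for f in truth.etf_by_scene)
        )
        from aquafoot.synthetic import field_masks

        masks = field_masks(noise_free_run["config"])
        crop_mask = np.zeros(scene.shape, dtype=bool)
        for m in masks.values():
            crop_mask |= m
        anchors = select_anchors(scene, crop_mask)
        assert anchors.t_hot_k == pytest.approx(320.0, abs=1e-6)
        assert anchors.t_cold_k == pytest.approx(295.0, abs=1e-6)

    def test_uniform_scene_is_degenerate(self):
        from aquafoot.raster import SceneRaster

        shape = (20, 20)
        scene = SceneRaster(
            scene_id="u", date=date(2016, 6, 1),
            lst_k=np.full(shape, 300.0),
            red=np.full(shape, 0.1), nir=np.full(shape, 0.4),
        )
        mask = np.zeros(shape, dtype=bool)
        mask[:10] = True
        with pytest.raises(ValueError, match="degenerate scene"):
            select_anchors(scene, mask)

    def test_translation_equivariance(self, noise_free_run):
        from aquafoot.raster import SceneRaster
        from aquafoot.synthetic import field_masks

        truth = noise_free_run["truth"]
        scene = next(
            sc for sc in noise_free_run["scenes"]
            if any(abs(truth.etf_by_scene[f][sc.scene_id] - 1.0) < 1e-12
                   for f in truth.etf_by_scene)
        )
        masks = field_masks(noise_free_run["config"])
        crop_mask = np.zeros(scene.shape, dtype=bool)
        for m in masks.values():
            crop_mask |= m
        shifted = SceneRaster(
            scene_id="s", date=scene.date, lst_k=scene.lst_k + 2.0,
            red=scene.red, nir=scene.nir,
        )
        a0 = select_anchors(scene, crop_mask)
        a2 = select_anchors(shifted, crop_mask)
        assert a2.t_hot_k == pytest.approx(a0.t_hot_k + 2.0, abs=1e-9)
        assert a2.t_cold_k == pytest.approx(a0.t_cold_k + 2.0, abs=1e-9)


class TestDailyAndSeasonalEt:
    def test_eta_linear_in_k_and_eto(self):
        etf = np.array([[1.0, 0.5], [0.25, NODATA]])
        eta = eta_daily(etf, 11.0)
        assert eta[0, 0] == pytest.approx(11.0)
        assert eta[1, 1] == NODATA
        np.testing.assert_allclose(eta_daily(etf, 11.0, k=0.5)[0], eta[0] / 2)
        assert np.all(eta_daily(etf, 0.0)[etf != NODATA] == 0.0)

    def _season(self, n=60, start=date(2016, 5, 1)):
        return [start + timedelta(days=i) for i in range(n)]

    def test_single_scene_full_fraction_gives_season_total(self):
        days = self._season()
        eto = np.full(len(days), 9.0)
        total = upscale_et_lgp([days[30]], [np.ones((3, 3))], days, eto)
        np.testing.assert_allclose(total, eto.sum())

    def test_two_scene_half_split(self):
        days = self._season(60)
        eto = np.full(60, 10.0)
        grids = [np.zeros((2, 2)), np.ones((2, 2))]
        total = upscale_et_lgp([days[14], days[44]], grids, days, eto)
        # days 0..29 go to the first scene (ETf 0), days 30..59 to the second
        np.testing.assert_allclose(total, 300.0)

    def test_against_day_loop_oracle(self):
        rng = np.random.default_rng(5)
        days = self._season(45)
        eto = rng.uniform(3, 15, len(days))
        scene_days = [days[3], days[20], days[40]]
        grids = [rng.uniform(0, 1, (8, 8)) for _ in scene_days]

        expected = np.zeros((8, 8))
        for d, e in zip(days, eto):
            dists = [abs((d - sd).days) for sd in scene_days]
            expected += e * grids[int(np.argmin(dists))]
        got = upscale_et_lgp(scene_days, grids, days, eto)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_no_scene_rejected(self):
        with pytest.raises(ValueError):
            upscale_et_lgp([], [], self._season(10), np.ones(10))


class TestYieldModel:
    def test_noiseless_recovery_of_reference_coefficients(self):
        model_ref = REFERENCE_YIELD_MODELS["maize"]
        rng = np.random.default_rng(1)
        savi = rng.uniform(0.1, 0.5, 60)
        y = model_ref.slope * savi + model_ref.intercept
        fit = fit_yield_model(savi, y, crop="maize", seed=11)
        assert fit.slope == pytest.approx(model_ref.slope, abs=1e-9)
        assert fit.intercept == pytest.approx(model_ref.intercept, abs=1e-9)
        assert fit.validation["r2"] == pytest.approx(1.0)
        assert fit.cross_validation["rmse_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_within_sampling_error(self):
        rng = np.random.default_rng(2)
        slopes = []
        true_slope, sigma, n = 44.265, 1.5, 100
        savi = rng.uniform(0.1, 0.5, n)
        se = sigma / (np.sqrt(0.6 * n) * savi.std())
        for seed in range(20):
            y = true_slope * savi + 11.147 + rng.normal(0, sigma, n)
            slopes.append(fit_yield_model(savi, y, seed=seed).slope)
        assert np.all(np.abs(np.array(slopes) - true_slope) < 3.5 * se)

    def test_split_determinism(self):
        rng = np.random.default_rng(3)
        savi = rng.uniform(0.1, 0.5, 30)
        y = 40 * savi + 10 + rng.normal(0, 1, 30)
        a = fit_yield_model(savi, y, seed=9)
        b = fit_yield_model(savi, y, seed=9)
        assert a.slope == b.slope and a.intercept == b.intercept

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_yield_model(np.full(20, 0.3), np.arange(20.0))
        with pytest.raises(ValueError):
            fit_yield_model(np.arange(5) / 10, np.arange(5.0))

    @pytest.mark.parametrize(
        "crop, savi, expected",
        [("maize", 0.0, 11.147), ("maize", 0.456, 31.33), ("carrot", 0.416, 41.97)],
    )
    def test_prediction_from_reference_coefficients(self, crop, savi, expected):
        grid = predict_yield(REFERENCE_YIELD_MODELS[crop], np.array([[savi]]))
        assert grid[0, 0] == pytest.approx(expected, abs=0.005)

    def test_prediction_floored_at_zero(self):
        model = REFERENCE_YIELD_MODELS["maize"]
        grid = predict_yield(model, np.array([[-2.0, NODATA]]))
        assert grid[0, 0] == 0.0 and grid[0, 1] == NODATA


class TestRsBlueWf:
    def test_same_arithmetic_as_field_accounting(self):
        wf = wf_rs_blue(np.array([[830.0]]), np.array([[29.59]]), "table")
        assert wf[0, 0] == pytest.approx(2805, abs=0.5)

    def test_zero_et_zero_wf_and_yield_floor(self):
        wf = wf_rs_blue(
            np.array([[0.0, 500.0]]), np.array([[20.0, 0.5]]), "equation",
            yield_floor_t_ha=1.0,
        )
        assert wf[0, 0] == 0.0
        assert wf[0, 1] == NODATA  # sub-floor yield masked, not divided

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            wf_rs_blue(np.ones((2, 2)), np.ones((3, 3)))

    def test_vectorized_equals_pixel_loop(self):
        rng = np.random.default_rng(8)
        et = rng.uniform(0, 900, (8, 8))
        yp = rng.uniform(0.5, 40, (8, 8))
        wf = wf_rs_blue(et, yp, "equation", yield_floor_t_ha=1.0)
        for i in range(8):
            for j in range(8):
                if yp[i, j] >= 1.0:
                    assert wf[i, j] == pytest.approx(et[i, j] * 10 / yp[i, j], rel=1e-12)
                else:
                    assert wf[i, j] == NODATA
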