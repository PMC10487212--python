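"""Distribution maps: flattening, masking, pixel-wise prediction, region
errors, Tukey letters, histogram statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from chemmap import calibration as cal
from chemmap import mapping as mp
from chemmap import synthetic as syn
from chemmap.hypercube import Hypercube


def linear_band_model(composition="mc", wavelengths=(495.0,), scale=1.0,
                      offset=0.0):
    """A CalibrationModel whose network is an (almost exactly) linear map of
    its first input band: tanh(eps*x)/eps ~ x to O(eps^2).

    Used to test the map plumbing, where mean-of-prediction must equal
    prediction-of-mean (linearity).
    """
    eps = 1e-6
    est = cal.MLPCalibrator(hidden_units=4)
    d = len(wavelengths)
    W1 = np.zeros((4, d))
    W1[0, 0] = eps
    theta = np.concatenate([W1.ravel(), np.zeros(4),
                            np.array([scale / eps, 0, 0, 0]), [offset]])
    est.theta_ = theta
    est.x_mean_ = np.zeros(d)
    est.x_std_ = np.ones(d)
    est.y_mean_, est.y_std_ = 0.0, 1.0
    est.stopping_record_ = {"reason": "constructed", "epochs": 0,
                            "optimizer": "none"}
    return cal.CalibrationModel(composition=composition,
                                wavelengths_nm=list(wavelengths), estimator=est,
                                replicate_id=0, seed=0)


class TestFlatten:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        cube = Hypercube(rng.random((2, 2, 3)), [420.0, 425.0, 430.0])
        flat, shape = mp.flatten_hypercube(cube)
        assert flat.shape == (4, 3)
        np.testing.assert_array_equal(mp.unflatten(flat, shape), cube.data)

    def test_row_major_pixel_order(self):
        rng = np.random.default_rng(1)
        cube = Hypercube(rng.random((5, 7, 2)), [500.0, 505.0])
        flat, _ = mp.flatten_hypercube(cube)
        for k in (0, 6, 13, 34):
            np.testing.assert_array_equal(flat[k], cube.data[k // 7, k % 7])

    @given(arrays(np.float64, (3, 4, 2), elements=st.floats(0, 1)))
    @settings(max_examples=20, deadline=None)
    def test_flatten_unflatten_property(self, data):
        cube = Hypercube(data, [600.0, 605.0])
        flat, shape = mp.flatten_hypercube(cube)
        np.testing.assert_array_equal(mp.unflatten(flat, shape), data)


class TestBackgroundMask:
    def test_fixed_threshold_recovers_generator_mask(self, small_field,
                                                     noiseless_optics):
        frames = syn.generate_hypercube(small_field, noiseless_optics, "vis",
                                        seed=0)
        from chemmap.preprocess import calibrate_reflectance
        refl = calibrate_reflectance(frames["raw"], frames["white"],
                                     frames["black"])
        mask = mp.background_mask(refl, method="fixed", threshold=0.2)
        np.testing.assert_array_equal(mask, small_field.mask)

    def test_all_foreground_image(self):
        mask = mp.background_mask(np.full((8, 8), 0.5), method="fixed",
                                  threshold=0.2)
        assert mask.all()

    def test_three_level_otsu_excludes_bright_fiducials(self):
        rng = np.random.default_rng(0)
        img = np.full((60, 60), 0.02)
        img[10:50, 10:50] = 0.4          # slice
        img[20:26, 20:26] = 0.95         # fiducial screw
        img = img + rng.normal(0, 0.01, img.shape)   # sensor noise
        mask = mp.background_mask(img, method="otsu", classes=3)
        assert mask[30, 40] and not mask[22, 22] and not mask[0, 0]

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mp.background_mask(np.zeros((5, 5)), method="fixed", threshold=0.5)


class TestPredictMap:
    grid = np.array([490.0, 495.0, 500.0])

    def _flat(self, shape=(4, 5)):
        rng = np.random.default_rng(0)
        cube = Hypercube(rng.random(shape + (3,)), self.grid)
        return cube, *mp.flatten_hypercube(cube)

    def test_identity_model_returns_band_image(self):
        cube, flat, shape = self._flat()
        model = linear_band_model(wavelengths=[495.0])
        mask = np.ones(shape, bool)
        dmap = mp.predict_map(model, flat, mask, shape, self.grid)
        np.testing.assert_allclose(dmap.values, cube.data[:, :, 1], atol=1e-9)

    def test_zero_mask_gives_all_sentinel(self):
        _, flat, shape = self._flat()
        dmap = mp.predict_map(linear_band_model(wavelengths=[495.0]), flat,
                              np.zeros(shape, bool), shape, self.grid)
        assert np.isnan(dmap.values).all()

    def test_missing_wavelength_error_lists_nm(self):
        _, flat, shape = self._flat()
        model = linear_band_model(wavelengths=[888.0])
        with pytest.raises(KeyError, match="888"):
            mp.predict_map(model, flat, np.ones(shape, bool), shape, self.grid)

    def test_masking_commutes_with_prediction(self):
        _, flat, shape = self._flat()
        model = linear_band_model(wavelengths=[495.0])
        mask = np.zeros(shape, bool)
        mask[1:3, 2:4] = True
        full = mp.predict_map(model, flat, mask, shape, self.grid)
        # predict only the foreground rows, then scatter
        fg_pred = model.estimator.predict(flat[mask.ravel()][:, [1]])
        np.testing.assert_allclose(full.values[mask], fg_pred, atol=1e-12)


class TestRegionErrors:
    def _setup(self, pred_value, ref_value):
        mask = syn.generate_chemistry_field(
            pd.DataFrame({"origin": 1, "fruit": 1, "region": range(1, 11),
                          "mc_pct": ref_value, "ssc_pct": 12.0, "ta_gpct": 0.9,
                          "cc_mg100gdm": 0.3}),
            raster_shape=(128, 128), mm_per_px=1.0).roi_mask()
        dmap = mp.DistributionMap(np.full((128, 128), float(pred_value)),
                                  np.ones((128, 128), bool), "mc", [495.0])
        ref = pd.DataFrame({"origin": 1, "fruit": 1, "region": range(1, 11),
                            "mc_pct": float(ref_value), "ssc_pct": 12.0,
                            "ta_gpct": 0.9, "cc_mg100gdm": 0.3})
        return {(1, 1): dmap}, {(1, 1): mask}, ref

    def test_exact_map_gives_zero_errors(self):
        maps, masks, ref = self._setup(86.0, 86.0)
        table, per_region = mp.regionwise_errors(maps, masks, ref, "mc")
        assert (table.mape_mean == 0).all()

    def test_ten_percent_error(self):
        maps, masks, ref = self._setup(11.0, 10.0)
        table, _ = mp.regionwise_errors(maps, masks, ref, "mc")
        np.testing.assert_allclose(table.mape_mean, 10.0, atol=1e-9)

    def test_table_is_per_region_over_fruit(self):
        maps, masks, ref = self._setup(86.0, 86.0)
        table, per_region = mp.regionwise_errors(maps, masks, ref, "mc")
        assert list(table.region) == list(range(1, 11))
        assert all(len(v) == 1 for v in per_region.values())


class TestTukeyRegions:
    def test_identical_groups_single_letter(self):
        groups = {r: np.full(12, 3.0) for r in range(1, 11)}
        assert set(mp.tukey_regions(groups).values()) == {"a"}

    def test_null_distribution_type_one_control(self):
        same = 0
        n = 150
        for seed in range(n):
            rng = np.random.default_rng(seed)
            groups = {r: rng.normal(10, 2, 12) for r in range(1, 11)}
            same += len(set(mp.tukey_regions(groups).values())) == 1
        assert same / n >= 0.9

    def test_shifted_region_gets_distinct_letter(self):
        rng = np.random.default_rng(0)
        groups = {r: rng.normal(10, 2, 12) for r in range(1, 11)}
        groups[7] = groups[7] + 10 * 2.0
        letters = mp.tukey_regions(groups)
        assert all(letters[7] != letters[r] for r in range(1, 11) if r != 7)

    def test_too_few_observations_rejected(self):
        groups = {r: np.array([1.0]) for r in range(1, 11)}
        with pytest.raises(ValueError, match="2 observations"):
            mp.tukey_regions(groups)


class TestHistogramStats:
    def test_symmetric_small_sample(self):
        dmap = mp.DistributionMap(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]),
                                  np.ones((1, 5), bool), "mc", [495.0])
        out = mp.map_histogram_stats(dmap)
        assert out["mean"] == pytest.approx(3.0)
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_flagged(self):
        dmap = mp.DistributionMap(np.full((3, 3), 7.0), np.ones((3, 3), bool),
                                  "mc", [495.0])
        out = mp.map_histogram_stats(dmap)
        assert out["degenerate"] and out["mean"] == 7.0
        assert out["skewness"] == out["kurtosis"] == 0.0

    def test_large_symmetric_map_near_zero_skew(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 1, (400, 250))
        dmap = mp.DistributionMap(vals, np.ones(vals.shape, bool), "mc", [495.0])
        out = mp.map_histogram_stats(dmap)
        assert abs(out["skewness"]) < 0.05
        assert out["kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_background_excluded_from_moments(self):
        vals = np.full((4, 4), np.nan)
        vals[:2, :2] = 5.0
        mask = ~np.isnan(vals)
        out = mp.map_histogram_stats(
            mp.DistributionMap(vals, mask, "mc", [495.0]))
        assert out["n_pixels"] == 4 and out["mean"] == 5.0


class TestMapPathEqualsTablePath:
    def test_roi_means_agree_with_direct_spectra_predictions(
            self, ref_table, small_field, noiseless_optics):
        """With a linear model and no noise, predicting pixel-wise and then
        averaging over an ROI equals predicting on the ROI-mean spectrum."""
        from chemmap.preprocess import calibrate_reflectance, extract_roi_mean_spectra
        frames = syn.generate_hypercube(small_field, noiseless_optics, "vis", seed=0)
        refl = calibrate_reflectance(frames["raw"], frames["white"], frames["black"])
        model = linear_band_model(composition="cc", wavelengths=[505.0],
                                  scale=-2.0, offset=1.4)
        flat, shape = mp.flatten_hypercube(refl)
        lab = small_field.roi_mask()
        dmap = mp.predict_map(model, flat, lab > 0, shape, refl.wavelengths)
        table = extract_roi_mean_spectra(refl, lab)
        direct = model.estimator.predict(table[["r0505"]].to_numpy())
        map_means = np.array([np.nanmean(dmap.values[lab == k])
                              for k in range(1, 11)])
        np.testing.assert_allclose(map_means, direct, atol=1e-6)
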