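"""Generators: reference tables, chemistry fields, hypercubes, landmarks,
availability tables."""

import io

import numpy as np
import pandas as pd
import pytest

from chemmap import registration as reg
from chemmap import synthetic as syn
from chemmap.preprocess import calibrate_reflectance

from conftest import random_affine


class TestReferenceTable:
    def test_full_design_shape_and_keys(self, ref_table):
        assert len(ref_table) == 600
        assert not ref_table.duplicated(["origin", "fruit", "region"]).any()
        assert ((ref_table.mc_pct > 0) & (ref_table.mc_pct < 100)).all()
        for col in ("ssc_pct", "ta_gpct", "cc_mg100gdm"):
            assert (ref_table[col] >= 0).all()

    def test_per_origin_means_converge_to_configured(self):
        # large per-origin n: sample means within 1% of configured means
        df = syn.generate_reference_table(design={"fruit_per_origin": 600,
                                                  "regions_per_fruit": 10},
                                          seed=3)
        for o, stats in syn.ORIGIN_STATS.items():
            got = df[df.origin == o].mc_pct.mean()
            assert got == pytest.approx(stats["mc"][0], rel=0.01)

    def test_seed_determinism_byte_identical_csv(self, tmp_path):
        a, b = io.StringIO(), io.StringIO()
        syn.write_reference_table(syn.generate_reference_table(seed=7), a)
        syn.write_reference_table(syn.generate_reference_table(seed=7), b)
        assert a.getvalue() == b.getvalue()

    def test_zero_sd_rejected_and_tiny_sd_warns(self):
        params = {o: dict(v) for o, v in syn.ORIGIN_STATS.items()}
        params[1]["mc"] = (86.51, 0.0)
        with pytest.raises(ValueError, match="SD"):
            syn.generate_reference_table(params=params, seed=0)
        params[1]["mc"] = (86.51, 1e-9)
        with pytest.warns(UserWarning, match="near-zero SD"):
            syn.generate_reference_table(params=params, correlations={}, seed=0,
                                         calibrate_pooled=False)

    def test_non_psd_correlations_rejected(self):
        bad = {("cc", "mc"): 0.95, ("cc", "ssc"): 0.95, ("mc", "ssc"): -0.95}
        with pytest.raises(ValueError, match="positive semi-definite"):
            syn.generate_reference_table(correlations=bad, seed=0,
                                         calibrate_pooled=False)

    def test_pooled_correlations_converge(self):
        # 6000-row table: pooled CC correlations within +-0.05 of configured
        df = syn.generate_reference_table(design={"fruit_per_origin": 100}, seed=1)
        got = syn.pooled_correlations(df)
        for pair, target in syn.POOLED_CORRELATIONS.items():
            assert got[pair] == pytest.approx(target, abs=0.05)


class TestChemistryField:
    def test_roi_means_match_reference(self, ref_table, small_field):
        rows = ref_table[(ref_table.origin == 1) & (ref_table.fruit == 1)]
        lab = small_field.roi_mask()
        for comp in syn.COMPOSITIONS:
            targets = rows.sort_values("region")[syn.COLUMN_OF[comp]].to_numpy()
            got = np.array([np.nanmean(small_field.fields[comp][lab == k])
                            for k in range(1, 11)])
            np.testing.assert_allclose(got, targets, atol=1e-6)

    def test_constant_roi_values_give_constant_field(self):
        rows = pd.DataFrame({
            "origin": 1, "fruit": 1, "region": range(1, 11),
            "mc_pct": 86.0, "ssc_pct": 12.0, "ta_gpct": 0.9, "cc_mg100gdm": 0.3,
        })
        fld = syn.generate_chemistry_field(rows, raster_shape=(128, 128), mm_per_px=1.0)
        inside = fld.fields["mc"][fld.mask]
        np.testing.assert_allclose(inside, 86.0, atol=1e-8)

    def test_axial_gradient_is_monotone(self):
        rows = pd.DataFrame({
            "origin": 1, "fruit": 1, "region": range(1, 11),
            "mc_pct": 86.0, "ssc_pct": 12.0, "ta_gpct": 0.9, "cc_mg100gdm": 0.3,
        })
        fld = syn.generate_chemistry_field(rows, raster_shape=(128, 128), mm_per_px=1.0,
                                           gradient_spec={"ssc": {"axial": 2.0}})
        # ROI means still honoured exactly under a gradient base
        lab = fld.roi_mask()
        got = np.array([np.nanmean(fld.fields["ssc"][lab == k]) for k in range(1, 11)])
        np.testing.assert_allclose(got, 12.0, atol=1e-6)
        # row means of the base+correction field decrease with row index (bottom
        # of image = low axial coordinate) away from the ROI corrections
        has_data = fld.mask.any(axis=1)
        col_mean = np.nanmean(fld.fields["ssc"][has_data], axis=1)
        valid = ~np.isnan(col_mean)
        smoothed = np.convolve(col_mean[valid], np.ones(9) / 9, mode="valid")
        assert smoothed[0] > smoothed[-1]

    def test_raster_too_small_raises(self, ref_table):
        rows = ref_table[(ref_table.origin == 1) & (ref_table.fruit == 1)]
        with pytest.raises(ValueError, match="cannot fit"):
            syn.generate_chemistry_field(rows, raster_shape=(64, 64), mm_per_px=1.0)


class TestHypercube:
    def test_noiseless_calibration_recovers_forward_model(self, small_field,
                                                          noiseless_optics):
        frames = syn.generate_hypercube(small_field, noiseless_optics, "vis", seed=0)
        refl = calibrate_reflectance(frames["raw"], frames["white"], frames["black"])
        chem = {c: np.where(small_field.mask,
                            np.nan_to_num(small_field.fields[c], nan=0.0), 0.0)
                for c in syn.COMPOSITIONS}
        expected = noiseless_optics.reflectance(frames["raw"].wavelengths, chem)
        expected[~small_field.mask] = 0.02
        np.testing.assert_allclose(refl.data, expected, atol=1e-12)

    def test_more_carotenoids_lower_reflectance_at_505(self, noiseless_optics):
        chem = {"mc": np.full(50, 86.0), "ssc": np.full(50, 12.0),
                "ta": np.full(50, 0.9), "cc": np.linspace(0.1, 0.5, 50)}
        chem_hi = dict(chem, cc=chem["cc"] + 0.1)
        r_lo = noiseless_optics.reflectance(np.array([505.0]), chem)
        r_hi = noiseless_optics.reflectance(np.array([505.0]), chem_hi)
        assert np.all(r_hi < r_lo)

    def test_edge_bands_have_inflated_noise(self, small_field):
        optics = syn.default_optics(noise_sd=0.01)
        resid_edge, resid_mid = [], []
        for seed in range(8):
            frames = syn.generate_hypercube(small_field, optics, "vis", seed=seed)
            raw = frames["raw"]
            i_edge = int(np.argmin(np.abs(raw.wavelengths - 385)))
            i_mid = int(np.argmin(np.abs(raw.wavelengths - 500)))
            # background pixels: constant signal, variance = noise variance
            bg = ~small_field.mask
            resid_edge.append(raw.data[bg, i_edge].std())
            resid_mid.append(raw.data[bg, i_mid].std())
        assert np.mean(resid_edge) > 3.0 * np.mean(resid_mid)


class TestLandmarkScene:
    def test_identity_zero_jitter_points_coincide(self, small_field):
        sc = syn.generate_landmark_scene(small_field, reg.Transform2D.identity(),
                                         seed=0, jitter_sd=0.0)
        np.testing.assert_allclose(sc.control_pairs[:, 0], sc.control_pairs[:, 1])
        np.testing.assert_allclose(sc.check_pairs[:, 0], sc.check_pairs[:, 1])

    def test_known_affine_recovered_from_scene(self, small_field):
        M = np.array([[1.02, 0.05, 3.0], [-0.04, 0.98, -2.0], [0, 0, 1.0]])
        sc = syn.generate_landmark_scene(small_field, reg.Transform2D("affine", M),
                                         seed=0, jitter_sd=0.0)
        fitted = reg.fit_transform(sc.control_pairs, "affine")
        np.testing.assert_allclose(fitted.matrix, M, atol=1e-9)

    def test_jittered_scene_check_rmse_in_range(self, small_field):
        rmses = []
        for seed in range(100):
            t = random_affine(np.random.default_rng(seed))
            sc = syn.generate_landmark_scene(small_field, t, seed=seed, jitter_sd=0.5)
            fitted = reg.fit_transform(sc.control_pairs, "affine")
            rmse, _ = reg.point_errors(fitted, sc.check_pairs)
            rmses.append(rmse)
        assert all(0.0 < r < 3.0 for r in rmses)

    def test_points_csv_round_trip(self, small_field, tmp_path):
        sc = syn.generate_landmark_scene(small_field, reg.Transform2D.identity(),
                                         seed=1, jitter_sd=0.5)
        path = tmp_path / "pts.csv"
        syn.write_points_csv(path, sc.control_pairs, sc.check_pairs)
        control, check = syn.read_points_csv(path)
        np.testing.assert_allclose(control, sc.control_pairs, atol=1e-6)
        np.testing.assert_allclose(check, sc.check_pairs, atol=1e-6)


class TestAvailabilityTable:
    def test_dense_grid_has_237_rows_all_available(self):
        df = syn.generate_availability_table("dense")
        assert len(df) == (1600 - 420) // 5 + 1 == 237
        assert df[["available_filter", "available_led", "available_laser"]].all().all()

    def test_file_round_trip_byte_identical(self, tmp_path):
        df = syn.generate_availability_table("sparse", seed=5)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        syn.write_availability_table(df, p1)
        again = syn.generate_availability_table("from_file", path=p1)
        syn.write_availability_table(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_rows_rejected_with_line_numbers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength,available_filter,available_led,available_laser\n"
                     "420,1,0,1\nnope,1,0\n430,2,0,1\n")
        with pytest.raises(ValueError, match=r"lines: \[3, 4\]"):
            syn.read_availability_table(p)

    def test_sparse_is_seed_deterministic(self):
        a = syn.generate_availability_table("sparse", seed=11)
        b = syn.generate_availability_table("sparse", seed=11)
        pd.testing.assert_frame_equal(a, b)
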