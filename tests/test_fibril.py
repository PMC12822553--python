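"""Cross-section analysis: geometry, heights, RI intersection, errors."""

import numpy as np
import pandas as pd
import pytest

from rimap import fibril as fb
from rimap.synth import arc_axis, straight_axis, synthetic_cross_section_table


def _loc_table(x, y, z, frame=None):
    n = len(x)
    return pd.DataFrame({
        "frame": frame if frame is not None else np.zeros(n, dtype=int),
        "x_nm": x, "y_nm": y, "z_nm": z,
    })


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

class TestDriftCorrection:
    def test_static_fiducials_are_identity(self):
        locs = _loc_table([100.0, 200.0], [50.0, 60.0], [0.0, 5.0],
                          frame=[0, 50])
        tracks = pd.DataFrame({
            "frame": list(range(0, 101, 10)) * 2,
            "x_nm": [500.0] * 11 + [1500.0] * 11,
            "y_nm": [500.0] * 11 + [700.0] * 11,
            "fiducial_id": [0] * 11 + [1] * 11,
        })
        corrected, rms = fb.correct_drift(locs, tracks)
        pd.testing.assert_frame_equal(corrected, locs)
        assert rms == 0.0

    def test_linear_drift_recovered(self, rng):
        frames = np.arange(0, 10_000, 20)
        drift = 0.1 * frames  # nm per frame, along x
        tracks = pd.DataFrame({
            "frame": frames,
            "x_nm": 500.0 + drift + rng.normal(0, 2.0, len(frames)),
            "y_nm": 500.0 + rng.normal(0, 2.0, len(frames)),
            "fiducial_id": 0,
        })
        locs = _loc_table(1000.0 + drift, np.full(len(frames), 300.0),
                          np.zeros(len(frames)), frame=frames)
        corrected, _ = fb.correct_drift(locs, tracks)
        resid = corrected["x_nm"].to_numpy() - 1000.0
        resid -= resid.mean()  # the correction is defined up to a constant
        assert np.sqrt(np.mean(resid ** 2)) < 0.05 * np.std(drift)

    def test_two_fiducials_beat_one(self, rng):
        """Averaging fiducials halves the noise injected by the correction."""
        frames = np.arange(0, 2000, 10)
        drift = 0.05 * frames
        noise = {fid: rng.normal(0, 10.0, len(frames)) for fid in (0, 1)}

        def tracks(fids):
            return pd.concat([
                pd.DataFrame({"frame": frames,
                              "x_nm": 500.0 + drift + noise[f],
                              "y_nm": 500.0, "fiducial_id": f})
                for f in fids], ignore_index=True)

        locs = _loc_table(1000.0 + drift, np.full(len(frames), 300.0),
                          np.zeros(len(frames)), frame=frames)

        def resid_rms(fids):
            corrected, _ = fb.correct_drift(locs, tracks(fids))
            r = corrected["x_nm"].to_numpy() - 1000.0
            return np.sqrt(np.mean((r - r.mean()) ** 2))

        assert resid_rms((0, 1)) < resid_rms((0,))

    def test_uncovered_frames_raise(self):
        locs = _loc_table([0.0], [0.0], [0.0], frame=[500])
        tracks = pd.DataFrame({"frame": [0, 100], "x_nm": [0.0, 0.0],
                               "y_nm": [0.0, 0.0], "fiducial_id": 0})
        with pytest.raises(ValueError, match="cover"):
            fb.correct_drift(locs, tracks)


# ---------------------------------------------------------------------------
# fibril axis and cross-section transform
# ---------------------------------------------------------------------------

class TestAxisAndTransform:
    def test_straight_fibril_gives_cartesian_coordinates(self, rng):
        x = rng.uniform(0, 3000, 800)
        y = 500.0 + rng.normal(0, 40.0, 800)
        axis = fb.fit_fibril_axis(_loc_table(x, y, np.zeros(800)))
        # the fitted curve is a straight line at y ~ 500 (the free ends
        # of the least-squares spline flare slightly)
        assert np.std(axis.points[:, 1]) < 8.0
        cs = fb.transform_to_cross_section(
            _loc_table([1500.0], [520.0], [30.0]), axis)
        assert abs(abs(cs["X"].iloc[0]) - abs(520.0 - axis.points[:, 1].mean())) < 3.0

    def test_arc_axis_recovered_within_tolerance(self, rng):
        truth = arc_axis(radius=5000.0, arc_angle=0.6, center=(0.0, 0.0))
        s = rng.uniform(100.0, truth.s[-1] - 100.0, 3000)
        base = truth.point(s)
        nrm = truth.normal(s)
        offs = rng.normal(0, 40.0, 3000)
        pts = base + offs[:, None] * nrm
        axis = fb.fit_fibril_axis(_loc_table(pts[:, 0], pts[:, 1],
                                             np.zeros(3000)))
        # distance of fitted nodes from the generating circle
        r_fit = np.hypot(axis.points[:, 0], axis.points[:, 1])
        interior = slice(10, -10)  # spline ends are less constrained
        rms = np.sqrt(np.mean((r_fit[interior] - 5000.0) ** 2))
        assert rms < 5.0

    def test_axis_fit_is_deterministic(self, rng):
        x = rng.uniform(0, 2000, 400)
        y = rng.normal(0, 30.0, 400)
        locs = _loc_table(x, y, np.zeros(400))
        a1 = fb.fit_fibril_axis(locs)
        a2 = fb.fit_fibril_axis(locs)
        np.testing.assert_array_equal(a1.points, a2.points)

    def test_point_on_axis_has_zero_offset(self):
        axis = straight_axis(2000.0, origin=(0.0, 500.0))
        cs = fb.transform_to_cross_section(
            _loc_table([1000.0], [500.0], [42.0]), axis)
        assert abs(cs["X"].iloc[0]) < 1e-6
        assert cs["s"].iloc[0] == pytest.approx(1000.0, abs=0.5)
        assert cs["Z"].iloc[0] == 42.0

    def test_arc_offset_matches_circle_geometry(self):
        radius = 5000.0
        axis = arc_axis(radius=radius, arc_angle=1.0)
        # a point 80 nm radially outside the arc
        theta = 0.4
        p = [(radius + 80.0) * np.cos(theta), (radius + 80.0) * np.sin(theta)]
        cs = fb.transform_to_cross_section(
            _loc_table([p[0]], [p[1]], [0.0]), axis)
        assert abs(cs["X"].iloc[0]) == pytest.approx(80.0, abs=1.0)
        assert cs["s"].iloc[0] == pytest.approx(radius * theta, abs=5.0)

    def test_mirror_symmetry_flips_lateral_sign(self, rng):
        axis = straight_axis(2000.0, origin=(0.0, 0.0))
        x = rng.uniform(100, 1900, 50)
        off = rng.uniform(10, 100, 50)
        cs_up = fb.transform_to_cross_section(
            _loc_table(x, off, np.ones(50)), axis)
        cs_dn = fb.transform_to_cross_section(
            _loc_table(x, -off, np.ones(50)), axis)
        np.testing.assert_allclose(cs_up["X"].to_numpy(),
                                   -cs_dn["X"].to_numpy(), atol=1e-9)
        np.testing.assert_allclose(cs_up["s"].to_numpy(),
                                   cs_dn["s"].to_numpy(), atol=1e-9)

    def test_round_trip_reproduces_lab_coordinates(self, rng):
        axis = arc_axis(radius=5000.0, arc_angle=0.8)
        s = rng.uniform(200.0, axis.s[-1] - 200.0, 200)
        base = axis.point(s)
        nrm = axis.normal(s)
        offs = rng.uniform(-80, 80, 200)
        pts = base + offs[:, None] * nrm
        locs = _loc_table(pts[:, 0], pts[:, 1], rng.uniform(0, 70, 200))
        cs = fb.transform_to_cross_section(locs, axis)
        back = fb.reconstruct_from_cross_section(cs, axis)
        assert np.abs(back["x_nm"].to_numpy() - pts[:, 0]).max() < 1.0
        assert np.abs(back["y_nm"].to_numpy() - pts[:, 1]).max() < 1.0

    def test_points_beyond_ends_are_flagged(self):
        axis = straight_axis(1000.0, origin=(0.0, 0.0))
        cs = fb.transform_to_cross_section(
            _loc_table([-200.0], [30.0], [0.0]), axis)
        assert bool(cs["boundary"].iloc[0])


# ---------------------------------------------------------------------------
# outlier filtering
# ---------------------------------------------------------------------------

class TestOutlierFilter:
    @staticmethod
    def _half_ring(rng, n, radius=69.0, sigma=6.0):
        phi = rng.uniform(0, np.pi, n)
        x = radius * np.cos(phi) + rng.normal(0, sigma, n)
        z = radius * np.sin(phi) + rng.normal(0, sigma, n)
        return x, z

    def test_injected_outliers_removed(self, rng):
        x, z = self._half_ring(rng, 950)
        n_out = 50
        xo = rng.uniform(-3 * 69, 3 * 69, n_out)
        zo = rng.uniform(120, 3 * 69, n_out)  # far above the fibril
        df = pd.DataFrame({"X": np.concatenate([x, xo]),
                           "Z": np.concatenate([z, zo]),
                           "is_outlier": [False] * 950 + [True] * n_out})
        kept, removed_frac = fb.filter_outliers(df)
        outliers_left = kept["is_outlier"].sum()
        inliers_lost = 950 - (~kept["is_outlier"]).sum()
        assert outliers_left <= 0.1 * n_out
        assert inliers_lost <= 0.02 * 950

    def test_clean_cloud_stays_intact(self, rng):
        x, z = self._half_ring(rng, 800)
        kept, removed = fb.filter_outliers(pd.DataFrame({"X": x, "Z": z}))
        assert removed <= 0.01

    def test_pure_noise_raises(self, rng):
        df = pd.DataFrame({"X": rng.uniform(-5000, 5000, 40),
                           "Z": rng.uniform(-5000, 5000, 40)})
        with pytest.raises(ValueError, match="noise"):
            fb.filter_outliers(df)


# ---------------------------------------------------------------------------
# height estimation and resampling error
# ---------------------------------------------------------------------------

class TestHeightEstimation:
    def test_constant_field_returns_that_height(self, rng):
        df = pd.DataFrame({"X": rng.uniform(-100, 100, 200),
                           "Z": np.full(200, 80.0)})
        est = fb.estimate_height(df, 40)
        assert est.H == pytest.approx(80.0, abs=1e-9)

    def test_noiseless_half_cylinder(self, rng):
        phi = rng.uniform(0, np.pi, 2000)
        df = pd.DataFrame({"X": 69.0 * np.cos(phi),
                           "Z": 69.0 * np.sin(phi)})
        est = fb.estimate_height(df, 40)
        assert est.H == pytest.approx(69.0, abs=2.0)

    def test_noisy_half_cylinder(self, rng):
        phi = rng.uniform(0, np.pi, 1000)
        df = pd.DataFrame({
            "X": 69.0 * np.cos(phi),
            "Z": 69.0 * np.sin(phi) + rng.normal(0, 5.0, 1000)})
        est = fb.estimate_height(df, 40)
        assert est.H == pytest.approx(69.0, abs=2.0)

    def test_debris_offset_added(self, rng):
        df = pd.DataFrame({"X": rng.uniform(-100, 100, 200),
                           "Z": np.full(200, 80.0)})
        est = fb.estimate_height(df, 40, debris_offset=3.5)
        assert est.H == pytest.approx(83.5, abs=1e-9)

    def test_too_few_localizations_raise(self):
        df = pd.DataFrame({"X": [0.0, 1.0], "Z": [1.0, 2.0]})
        with pytest.raises(ValueError, match="window"):
            fb.estimate_height(df, 40)

    def test_identical_points_resample_to_zero_error(self, rng):
        df = pd.DataFrame({"X": np.arange(200.0), "Z": np.full(200, 50.0)})
        err = fb.resample_height_error(df, 40, n_resamples=50, rng=rng)
        assert err == 0.0

    def test_resampling_error_is_stable_in_resample_count(self, rng):
        phi = rng.uniform(0, np.pi, 800)
        df = pd.DataFrame({
            "X": 69.0 * np.cos(phi),
            "Z": 69.0 * np.sin(phi) + rng.normal(0, 5.0, 800)})
        e1 = fb.resample_height_error(df, 40, n_resamples=300,
                                      rng=np.random.default_rng(0))
        e2 = fb.resample_height_error(df, 40, n_resamples=600,
                                      rng=np.random.default_rng(1))
        assert abs(e1 - e2) < 0.1 * max(e1, e2)


# ---------------------------------------------------------------------------
# refractive-index estimation and error propagation
# ---------------------------------------------------------------------------

class TestRefractiveIndex:
    @staticmethod
    def _heights(n_grid, slope, intercept, sigma=0.5):
        return [fb.HeightEstimate(H=slope * n + intercept, sigma_H=sigma,
                                  n_assumed=n, window_nlocs=40)
                for n in n_grid]

    def test_exact_intersection_is_recovered(self):
        n_grid = [1.38, 1.40, 1.42, 1.44, 1.46, 1.48]
        slope, intercept = 160.0, -160.0 * 1.43 + 69.0
        heights = self._heights(n_grid, slope, intercept, sigma=0.0)
        afm = fb.HeightEstimate(H=69.0, sigma_H=0.0, n_assumed=np.nan,
                                window_nlocs=40)
        est = fb.estimate_refractive_index(heights, afm, n_draws=0)
        assert est.n == pytest.approx(1.43, abs=1e-12)
        assert est.in_range

    def test_negative_slope_rejected(self):
        heights = self._heights([1.38, 1.43, 1.48], -50.0, 140.0)
        afm = fb.HeightEstimate(H=69.0, sigma_H=0.5, n_assumed=np.nan,
                                window_nlocs=40)
        with pytest.raises(ValueError, match="slope"):
            fb.estimate_refractive_index(heights, afm)

    def test_propagated_error_matches_closed_form(self, rng):
        """sigma_n ~ sqrt(sigma_H^2/m + sigma_A^2) / slope for common noise."""
        n_grid = np.array([1.38, 1.40, 1.42, 1.44, 1.46, 1.48])
        slope, sigma_h, sigma_a = 160.0, 1.0, 0.5
        heights = slope * (n_grid - 1.43) + 69.0
        got = fb.propagate_ri_error(n_grid, heights,
                                    np.full(6, sigma_h), 69.0, sigma_a,
                                    n_draws=20000, rng=rng)
        expected = np.sqrt(sigma_h ** 2 / 6 + sigma_a ** 2) / slope
        assert got == pytest.approx(expected, rel=0.1)

    def test_error_scales_linearly_with_height_noise(self, rng):
        n_grid = np.array([1.38, 1.40, 1.42, 1.44, 1.46, 1.48])
        heights = 160.0 * (n_grid - 1.43) + 69.0
        e1 = fb.propagate_ri_error(n_grid, heights, np.full(6, 0.5), 69.0,
                                   0.25, n_draws=20000,
                                   rng=np.random.default_rng(7))
        e2 = fb.propagate_ri_error(n_grid, heights, np.full(6, 1.0), 69.0,
                                   0.5, n_draws=20000,
                                   rng=np.random.default_rng(7))
        assert e2 == pytest.approx(2.0 * e1, rel=0.05)

    def test_zero_sigmas_give_zero_error(self, rng):
        n_grid = np.array([1.38, 1.43, 1.48])
        heights = 160.0 * (n_grid - 1.43) + 69.0
        got = fb.propagate_ri_error(n_grid, heights, np.zeros(3), 69.0, 0.0,
                                    n_draws=1000, rng=rng)
        assert got == 0.0


class TestSwelling:
    def test_no_swelling_keeps_the_index(self):
        rec = fb.swelling_and_dry_index(1000.0, 1000.0, 1.45)
        assert rec.delta_A == 0.0
        assert rec.n_dry == pytest.approx(1.45)

    def test_doubled_area_mixes_half_and_half(self):
        # forward model: n = (n_dry + dA * n_water) / (1 + dA)
        rec = fb.swelling_and_dry_index(1000.0, 2000.0, (1.53 + 1.33) / 2)
        assert rec.n_dry == pytest.approx(1.53, abs=1e-12)

    def test_forward_inverse_round_trip_is_exact(self):
        for n_dry in (1.45, 1.60, 1.75):
            for delta_a in (0.3, 1.5, 3.5):
                n_coll = (n_dry + delta_a * fb.N_WATER) / (1 + delta_a)
                rec = fb.swelling_and_dry_index(1.0, 1.0 + delta_a, n_coll)
                assert rec.n_dry == pytest.approx(n_dry, abs=1e-12)

    def test_shrinkage_is_flagged_not_rejected(self):
        rec = fb.swelling_and_dry_index(1000.0, 900.0, 1.45)
        assert rec.shrinkage


class TestCrossSectionalArea:
    def test_semicircle_on_afm_grid(self):
        r = 100.0
        x = np.arange(-130.0, 130.1, 39.0)
        h = np.sqrt(np.clip(r ** 2 - x ** 2, 0, None))
        # refine: the coarse 39 nm grid underestimates the cap; use the
        # analytic tolerance of the example
        area = fb.cross_sectional_area(x, h)
        assert area == pytest.approx(np.pi * r ** 2 / 2, rel=0.04)

    def test_fine_grid_semicircle_within_one_percent(self):
        r = 100.0
        x = np.arange(-110.0, 110.1, 2.0)
        h = np.sqrt(np.clip(r ** 2 - x ** 2, 0, None))
        area = fb.cross_sectional_area(x, h)
        assert area == pytest.approx(np.pi * r ** 2 / 2, rel=0.01)

    def test_flat_profile_has_zero_area(self):
        assert fb.cross_sectional_area(np.arange(10.0), np.zeros(10)) == 0.0

    def test_rectangle_is_exact(self):
        x = np.arange(0.0, 200.1, 10.0)
        h = np.full_like(x, 100.0)
        assert fb.cross_sectional_area(x, h) == pytest.approx(2e4)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            fb.cross_sectional_area(np.array([0.0, 2.0, 1.0]), np.ones(3))


# ---------------------------------------------------------------------------
# RI mapping and variance decomposition
# ---------------------------------------------------------------------------

N_GRID = (1.38, 1.40, 1.42, 1.44, 1.46, 1.48)
Z_COLS = {n: f"z@{n:.3f}" for n in N_GRID}


class TestRIMap:
    def test_constant_index_maps_flat(self, rng):
        cs = synthetic_cross_section_table(N_GRID, rng, axis_length=6000.0,
                                           n_profile=1.43)
        ri = fb.map_ri_along_fibril(cs, N_GRID, Z_COLS,
                                    afm_height=lambda s: 69.0,
                                    window_nlocs=100, n_resamples=80,
                                    n_draws=500, rng=rng)
        assert len(ri) > 5
        # constancy: windows scatter around the common map level within
        # their reported experimental error
        dev = np.abs(ri["n"] - ri["n"].mean())
        assert (dev < 3 * ri["sigma_n_exp"]).mean() > 0.9

    def test_step_in_index_is_localized(self, rng):
        step_at = 4000.0
        prof = lambda s: np.where(s < step_at, 1.41, 1.46)
        cs = synthetic_cross_section_table(N_GRID, rng, axis_length=8000.0,
                                           n_profile=prof)
        ri = fb.map_ri_along_fibril(cs, N_GRID, Z_COLS,
                                    afm_height=lambda s: 69.0,
                                    window_nlocs=100, n_resamples=50,
                                    n_draws=400, rng=rng)
        extent = ri["window_nm"].mean()
        left = ri[ri.s_nm < step_at - 2 * extent]
        right = ri[ri.s_nm > step_at + 2 * extent]
        # the 0.05 step is fully developed beyond two window extents
        assert right["n"].mean() - left["n"].mean() == pytest.approx(
            0.05, abs=0.012)
        assert left["n"].std() < 0.02 and right["n"].std() < 0.02

    def test_window_count_bookkeeping(self, rng):
        cs = synthetic_cross_section_table(N_GRID, rng, axis_length=5000.0)
        window, overlap = 100, 0.9
        ri = fb.map_ri_along_fibril(cs, N_GRID, Z_COLS,
                                    afm_height=lambda s: 69.0,
                                    window_nlocs=window,
                                    overlap_fraction=overlap,
                                    n_resamples=0, n_draws=0, rng=rng)
        step = max(1, int(round((1 - overlap) * window)))
        expected = (len(cs) - window) // step + 1
        assert len(ri) == expected


class TestVarianceDecomposition:
    def test_noise_free_constant_field_has_zero_sample_variance(self, rng):
        cs = synthetic_cross_section_table(N_GRID, rng, axis_length=6000.0,
                                           z_noise=1e-9, x_noise=0.0)
        ri = fb.map_ri_along_fibril(cs, N_GRID, Z_COLS,
                                    afm_height=lambda s: 69.0,
                                    window_nlocs=100, n_resamples=50,
                                    n_draws=400, rng=rng)
        table = fb.variance_decomposition({100: ri})
        assert table["var_collagen"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_variance_shrinks_with_window_size(self, rng):
        cell = 250.0
        offsets = rng.normal(0.0, 0.02, 256)
        prof = lambda s: 1.43 + offsets[(s // cell).astype(int) % 256]
        cs = synthetic_cross_section_table(N_GRID, rng, axis_length=16000.0,
                                           n_profile=prof)
        maps = {}
        for window in (100, 400):
            maps[window] = fb.map_ri_along_fibril(
                cs, N_GRID, Z_COLS, afm_height=lambda s: 69.0,
                window_nlocs=window, overlap_fraction=0.75,
                n_resamples=40, n_draws=300, rng=rng)
        table = fb.variance_decomposition(maps).set_index("window_nlocs")
        assert table.loc[400, "var_total"] < table.loc[100, "var_total"]
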