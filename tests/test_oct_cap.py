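import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquefuse.errors import ConfigurationError, SegmentationError
from plaquefuse.oct_cap import (Contour, PolarOctFrame,
                                RepresentativeSamplingConfig, Roi,
                                SegmentationParams, extract_contour,
                                lumen_area, polar_cost_image,
                                representative_thickness,
                                segment_cap_abluminal, segment_lumen,
                                thickness_profile, ThicknessProfile)
from .conftest import truth_thickness_at_profile
from .oracles import brute_force_path


def step_image(n_alines, n_radial, k):
    img = np.zeros((n_alines, n_radial))
    img[:, k:] = 1.0
    return img


class TestCostImage:
    def test_rising_step_minimum_at_edge(self):
        cost = polar_cost_image(step_image(4, 20, 7), "dark_to_bright")
        mins = set(np.argmin(cost, axis=1))
        assert mins <= {6, 7}                      # centered gradient straddles the step
        assert np.all(np.min(cost, axis=1) == 0.0)

    def test_polarity_selects_edge_direction(self):
        img = step_image(4, 30, 7) - step_image(4, 30, 20)  # up at 7, down at 20
        up = polar_cost_image(img, "dark_to_bright")
        down = polar_cost_image(img, "bright_to_dark")
        assert set(np.argmin(up, axis=1)) <= {6, 7}
        assert set(np.argmin(down, axis=1)) <= {19, 20}

    def test_constant_image_gives_uniform_unit_cost(self):
        cost = polar_cost_image(np.full((5, 12), 3.3), "dark_to_bright")
        assert np.array_equal(cost, np.ones((5, 12)))

    def test_cost_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        cost = polar_cost_image(rng.random((16, 40)), "bright_to_dark", sigma=1.0)
        assert cost.min() >= 0.0 and cost.max() <= 1.0

    def test_noise_free_frame_argmin_tracks_truth_lumen(self, clean_truth,
                                                        clean_pullback):
        frame = clean_pullback.frame(60)
        cost = polar_cost_image(frame, "dark_to_bright")
        argmin_um = (np.argmin(cost, axis=1) + 0.5) * frame.radial_pixel_um
        err = np.abs(argmin_um - clean_truth.lumen_radius_um[60])
        assert err.max() <= 1.5 * frame.radial_pixel_um


class TestExtractContour:
    def test_zero_smoothness_is_per_column_argmin(self):
        rng = np.random.default_rng(1)
        cost = rng.random((15, 9))
        c = extract_contour(cost, smoothness=0.0, max_step=9)
        assert np.array_equal(c.radius_um - 0.5, np.argmin(cost, axis=1))

    def test_zero_smoothness_ties_break_to_smaller_radius(self):
        cost = np.zeros((4, 6))
        c = extract_contour(cost, smoothness=0.0, max_step=6)
        assert np.all(c.radius_um - 0.5 == 0)

    def test_large_smoothness_flattens_to_best_constant_row(self):
        rng = np.random.default_rng(2)
        cost = rng.random((12, 8))
        c = extract_contour(cost, smoothness=1e6, max_step=8)
        path = (c.radius_um - 0.5).astype(int)
        assert np.all(path == path[0])
        assert path[0] == int(np.argmin(cost.sum(axis=0)))

    @pytest.mark.parametrize("closed", [False, True])
    def test_matches_brute_force_on_small_grids(self, closed):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n_cols = int(rng.integers(2, 9))
            n_r = int(rng.integers(2, 13))
            lam = float(rng.uniform(0, 1.5))
            m = int(rng.integers(1, 4))
            cost = rng.random((n_cols, n_r))
            c = extract_contour(cost, smoothness=lam, max_step=m, closed=closed)
            oracle_cost, _ = brute_force_path(cost, lam, m, closed)
            assert c.path_cost == pytest.approx(oracle_cost, abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_open_path_optimal_property(self, seed):
        rng = np.random.default_rng(seed)
        n_cols = int(rng.integers(2, 8))
        n_r = int(rng.integers(2, 10))
        lam = float(rng.uniform(0, 1.0))
        m = int(rng.integers(1, 3))
        cost = rng.random((n_cols, n_r))
        c = extract_contour(cost, smoothness=lam, max_step=m)
        oracle_cost, _ = brute_force_path(cost, lam, m, False)
        assert c.path_cost == pytest.approx(oracle_cost, abs=1e-9)

    def test_infeasible_window_raises(self):
        cost = np.full((3, 5), np.inf)
        with pytest.raises(SegmentationError):
            extract_contour(cost, smoothness=0.5, max_step=1)

    def test_closed_wrap_step_bound_holds(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            cost = rng.random((9, 11))
            c = extract_contour(cost, smoothness=0.3, max_step=2, closed=True)
            path = (c.radius_um - 0.5).astype(int)
            assert abs(path[0] - path[-1]) <= 2
            assert np.all(np.abs(np.diff(path)) <= 2)


class TestLumenSegmentation:
    def test_noise_free_recovery_within_one_pixel(self, clean_truth, clean_pullback):
        for i in (10, 60, 100):
            frame = clean_pullback.frame(i)
            lum = segment_lumen(frame)
            err = np.abs(lum.radius_um - clean_truth.lumen_radius_um[i])
            assert err.max() <= frame.radial_pixel_um

    def test_speckle_recovery_mean_within_three_pixels(self, speckle_truth,
                                                       speckle_pullback):
        for i in (10, 60, 100):
            frame = speckle_pullback.frame(i)
            lum = segment_lumen(frame)
            err = np.abs(lum.radius_um - speckle_truth.lumen_radius_um[i])
            assert err.mean() <= 3 * frame.radial_pixel_um

    def test_rotation_equivariance_under_circular_shift(self, speckle_pullback):
        """Rotating the frame rotates the contour; degenerate cost ties may
        resolve differently, so equality is required up to optimal-path
        degeneracy (identical path cost, radii within one pixel)."""
        frame = speckle_pullback.frame(60)
        shift = 71
        shifted = PolarOctFrame(np.roll(frame.intensity, shift, axis=0),
                                frame.radial_pixel_um)
        lum = segment_lumen(frame)
        lum_shifted = segment_lumen(shifted)
        assert lum_shifted.path_cost == pytest.approx(lum.path_cost, rel=1e-9)
        diff = np.abs(np.roll(lum.radius_um, shift) - lum_shifted.radius_um)
        assert diff.max() <= frame.radial_pixel_um
        assert np.mean(diff == 0) >= 0.95


class TestCapSegmentation:
    def test_constant_cap_recovered_within_20_um(self):
        from plaquefuse.phantom import CapField, PhantomConfig, \
            make_phantom_vessel, render_oct_pullback
        cfg = PhantomConfig(noise=0.0, n_alines=360, rotation_drift_deg_per_frame=0.0,
                            cap_thickness_field=CapField("constant",
                                                         {"thickness_um": 200.0}))
        truth = make_phantom_vessel(cfg)
        pb = render_oct_pullback(truth)
        roi = truth.cap_roi(margin_deg=0.0)
        frame = pb.frame(60)
        lum = segment_lumen(frame)
        abl = segment_cap_abluminal(frame, roi, lum, SegmentationParams())
        sep = abl.radius_um - lum.radius_um[abl.alines]
        inside = np.isfinite(truth.abluminal_radius_um[60, abl.alines])
        assert np.all(np.abs(sep[inside] - 200.0) <= 20.0)

    def test_single_aline_roi_gives_single_point(self, clean_pullback):
        frame = clean_pullback.frame(60)
        lum = segment_lumen(frame)
        roi = Roi(60, 60, 150, 150)
        abl = segment_cap_abluminal(frame, roi, lum)
        assert abl.alines.size == 1

    def test_abluminal_always_deeper_than_lumen_plus_offset(self, speckle_truth,
                                                            speckle_pullback):
        roi = speckle_truth.cap_roi()
        params = SegmentationParams()
        frame = speckle_pullback.frame(55)
        lum = segment_lumen(frame, params)
        abl = segment_cap_abluminal(frame, roi, lum, params)
        assert np.all(abl.radius_um > lum.radius_um[abl.alines]
                      + params.min_offset_um - frame.radial_pixel_um)

    def test_no_admissible_path_raises(self, clean_pullback):
        frame = clean_pullback.frame(60)
        lum = segment_lumen(frame)
        params = SegmentationParams(min_offset_um=1e6)  # window beyond scan depth
        with pytest.raises(SegmentationError):
            segment_cap_abluminal(frame, Roi(60, 60, 100, 140), lum, params)


class TestThickness:
    def circle_contour(self, r_um, n=360):
        return Contour(np.arange(n), np.full(n, float(r_um)), n, True)

    def test_concentric_circles_thickness_is_radius_difference(self):
        prof = thickness_profile(self.circle_contour(1000.0),
                                 self.circle_contour(1200.0))
        assert np.allclose(prof.thickness_um, 200.0, atol=1e-3)

    def test_identical_contours_give_zero_thickness(self):
        prof = thickness_profile(self.circle_contour(1000.0),
                                 self.circle_contour(1000.0))
        assert np.allclose(prof.thickness_um, 0.0, atol=1e-9)

    def test_open_lumen_rejected(self):
        open_lumen = Contour(np.arange(10), np.full(10, 900.0), 360, False)
        with pytest.raises(ConfigurationError):
            thickness_profile(open_lumen, self.circle_contour(1100.0))

    def test_gaussian_dip_minimum_recovered_within_20_um(self, clean_truth,
                                                         clean_pullback):
        roi = clean_truth.cap_roi()
        measured_min = np.inf
        for i in range(roi.frame_first, roi.frame_last + 1, 2):
            frame = clean_pullback.frame(i)
            lum = segment_lumen(frame)
            abl = segment_cap_abluminal(frame, roi, lum)
            prof = thickness_profile(lum, abl)
            prof.frame_index = i
            inside = np.isfinite(truth_thickness_at_profile(clean_truth, prof))
            vals = prof.thickness_um[inside & prof.valid]
            if vals.size:
                measured_min = min(measured_min, vals.min())
        assert measured_min == pytest.approx(100.0, abs=20.0)


class TestRepresentativeThickness:
    def make_profiles(self, thickness_fn, n_frames=13, n_sites=100, dz=0.5):
        out = []
        for i in range(n_frames):
            z = i * dz
            out.append(ThicknessProfile(
                alines=np.arange(n_sites),
                thickness_um=np.full(n_sites, thickness_fn(z)),
                frame_index=i, z_mm=z))
        return out

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_constant_cap_gives_exact_constant(self, seed):
        profiles = self.make_profiles(lambda z: 200.0)
        cfg = RepresentativeSamplingConfig(seed=seed)
        assert representative_thickness(profiles, cfg) == pytest.approx(200.0)

    def test_spacing_larger_than_plaque_uses_single_frame(self):
        profiles = self.make_profiles(lambda z: 100.0 + 10 * z, n_frames=4, dz=0.2)
        cfg = RepresentativeSamplingConfig(spacing_mm=50.0)
        assert representative_thickness(profiles, cfg) == pytest.approx(100.0)

    def test_linear_ramp_averages_to_midpoint(self):
        # 100 -> 300 um over 6 mm, sampled every 0.5 mm: mean 200 um
        profiles = self.make_profiles(lambda z: 100.0 + (300.0 - 100.0) * z / 6.0)
        vals = [representative_thickness(profiles,
                                         RepresentativeSamplingConfig(seed=s))
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(200.0, abs=5.0)

    def test_narrow_roi_warns_and_uses_all_sites(self):
        profiles = self.make_profiles(lambda z: 150.0, n_sites=3)
        with pytest.warns(UserWarning, match="sites"):
            val = representative_thickness(profiles,
                                           RepresentativeSamplingConfig(seed=0))
        assert val == pytest.approx(150.0)


class TestLumenArea:
    def circle(self, r_um, n=968):
        return Contour(np.arange(n), np.full(n, float(r_um)), n, True)

    def test_circle_area(self):
        assert lumen_area(self.circle(1500.0)) == pytest.approx(
            np.pi * 1.5 ** 2, rel=1e-3)

    def test_ellipse_area(self):
        n = 968
        t = np.deg2rad(np.arange(n) * 360.0 / n)
        r = 2.0 * 1.0 / np.sqrt((1.0 * np.cos(t)) ** 2 + (2.0 * np.sin(t)) ** 2)
        c = Contour(np.arange(n), r * 1000, n, True)
        assert lumen_area(c) == pytest.approx(np.pi * 2.0 * 1.0, rel=1e-3)

    def test_area_scales_quadratically_with_radius(self):
        a1 = lumen_area(self.circle(1000.0))
        a2 = lumen_area(self.circle(2000.0))
        assert a2 == pytest.approx(4 * a1, rel=1e-12)

    def test_open_contour_rejected(self):
        c = Contour(np.arange(10), np.full(10, 1000.0), 360, False)
        with pytest.raises(ConfigurationError):
            lumen_area(c)
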