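import numpy as np
import pytest

from plaquefuse.coregister import (Landmark, Registration, area_agreement,
                                   axial_map, length_agreement,
                                   resample_cap_to_grid, rotational_map,
                                   wrap_angle_deg)
from plaquefuse.errors import ConfigurationError, RegistrationError
from plaquefuse.grids import BinGrid
from plaquefuse.oct_cap import ThicknessProfile


def lm(frame, s, map_deg=None, oct_deg=None, label="x"):
    return Landmark(label=label, frame_index=frame, s_mm=s,
                    map_orientation_deg=map_deg, oct_orientation_deg=oct_deg)


class TestAxial:
    def test_linear_midpoint(self):
        reg = axial_map([lm(10, 2.0), lm(110, 21.0)])
        assert reg.frame_to_s(60) == pytest.approx(11.5)

    def test_anchors_interpolated_exactly(self):
        reg = axial_map([lm(10, 2.0), lm(50, 8.0), lm(110, 21.0)])
        assert reg.frame_to_s(10) == 2.0
        assert reg.frame_to_s(50) == 8.0
        assert reg.frame_to_s(110) == 21.0

    def test_collinear_third_anchor_changes_nothing(self):
        reg2 = axial_map([lm(0, 0.0), lm(100, 20.0)])
        reg3 = axial_map([lm(0, 0.0), lm(50, 10.0), lm(100, 20.0)])
        f = np.arange(-20, 140)
        assert np.allclose(reg2.frame_to_s(f), reg3.frame_to_s(f))

    def test_extrapolation_linear_at_ends(self):
        reg = axial_map([lm(10, 2.0), lm(110, 21.0)])
        assert reg.frame_to_s(0) == pytest.approx(2.0 - 10 * 0.19)
        assert reg.frame_to_s(120) == pytest.approx(21.0 + 10 * 0.19)

    def test_monotone_everywhere(self):
        reg = axial_map([lm(10, 2.0), lm(40, 5.0), lm(110, 21.0)])
        s = reg.frame_to_s(np.arange(0, 130))
        assert np.all(np.diff(s) > 0)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(RegistrationError):
            axial_map([lm(10, 5.0), lm(110, 2.0)])

    def test_single_anchor_rejected(self):
        with pytest.raises(RegistrationError):
            axial_map([lm(10, 2.0)])


class TestRotational:
    def make(self, offA, offB, fA=10, fB=110):
        a = lm(fA, 2.0, map_deg=offA, oct_deg=0.0, label="a")
        b = lm(fB, 21.0, map_deg=offB, oct_deg=0.0, label="b")
        return rotational_map(a, b, axial_map([a, b]))

    def test_linear_interpolation_midpoint(self):
        reg = self.make(10.0, 30.0)
        assert reg.rotation_offset(60) == pytest.approx(20.0)

    def test_equal_offsets_constant(self):
        reg = self.make(25.0, 25.0)
        assert np.allclose(np.atleast_1d(reg.rotation_offset(np.arange(0, 150))), 25.0)

    def test_constant_extrapolation_outside_anchors(self):
        reg = self.make(10.0, 30.0)
        assert reg.rotation_offset(0) == 10.0
        assert reg.rotation_offset(140) == 30.0

    def test_wrap_seam_interpolates_through_180(self):
        reg = self.make(170.0, -170.0)
        assert reg.rotation_offset(10) == 170.0
        assert reg.rotation_offset(110) == pytest.approx(-170.0) or \
            reg.rotation_offset(110) == pytest.approx(190.0)
        assert reg.rotation_offset(60) == pytest.approx(180.0)
        # never passes through 0
        mid = np.atleast_1d(reg.rotation_offset(np.arange(10, 111)))
        assert np.all(np.abs(mid) >= 170.0 - 1e-9)

    def test_phantom_drift_recovered_within_1_degree(self, clean_truth):
        lms = clean_truth.landmarks()
        reg = rotational_map(lms[0], lms[1], axial_map(lms))
        frames = np.arange(clean_truth.frame_z_mm.size)
        rec = np.atleast_1d(reg.rotation_offset(frames))
        truth_off = clean_truth.rotation_offset_deg
        fa, fb = reg.rot_anchor_frames
        between = (frames >= fa) & (frames <= fb)
        err = np.abs(wrap_angle_deg(rec - truth_off))
        assert err[between].max() <= 1.0
        assert err[frames == fa][0] == 0.0
        assert err[frames == fb][0] == 0.0

    def test_missing_orientation_rejected(self):
        a = lm(10, 2.0, map_deg=10.0, oct_deg=None)
        b = lm(110, 21.0, map_deg=30.0, oct_deg=0.0)
        with pytest.raises(RegistrationError):
            rotational_map(a, b, axial_map([a, b]))


class TestResampling:
    def identity_reg(self, offset=0.0, n_frames=121, inter_mm=0.2):
        return Registration(
            anchor_frames=np.array([0.0, n_frames - 1.0]),
            anchor_s_mm=np.array([0.0, (n_frames - 1) * inter_mm]),
            rot_anchor_frames=(0, n_frames - 1),
            rot_anchor_offsets_deg=(offset, offset))

    def profiles(self, value=200.0, frames=range(45, 76), n_alines=360):
        out = []
        for i in frames:
            alines = np.arange(100, 240)
            out.append(ThicknessProfile(alines=alines,
                                        thickness_um=np.full(alines.size, value),
                                        frame_index=i, z_mm=i * 0.2))
        return out

    def test_constant_cap_fills_bins_with_constant(self):
        grid = BinGrid(length_mm=24.0)
        cap = resample_cap_to_grid(self.profiles(), self.identity_reg(), grid, 360)
        assert cap.covered.any()
        assert np.allclose(cap.values[cap.covered], 200.0)

    def test_rotating_registration_shifts_angular_bins(self):
        grid = BinGrid(length_mm=24.0)
        c0 = resample_cap_to_grid(self.profiles(), self.identity_reg(0.0), grid, 360)
        c90 = resample_cap_to_grid(self.profiles(), self.identity_reg(90.0), grid, 360)
        assert np.array_equal(np.roll(c0.counts, 9, axis=1), c90.counts)

    def test_sample_count_conserved(self):
        grid = BinGrid(length_mm=24.0)
        profiles = self.profiles()
        cap = resample_cap_to_grid(profiles, self.identity_reg(), grid, 360)
        assert cap.counts.sum() == sum(p.valid.sum() for p in profiles)

    def test_phantom_cap_map_within_25_um_of_truth(self, clean_truth,
                                                   pipeline_clean_capmap):
        capmap, truth_map = pipeline_clean_capmap
        both = capmap.covered & np.isfinite(truth_map)
        err = np.abs(capmap.values[both] - truth_map[both])
        assert err.mean() <= 25.0


@pytest.fixture(scope="session")
def pipeline_clean_capmap(clean_truth, clean_pullback):
    """Cap map measured end-to-end on the noise-free phantom, plus the
    truth field binned at the same sample positions."""
    from plaquefuse.oct_cap import (segment_cap_abluminal, segment_lumen,
                                    thickness_profile)
    from plaquefuse.grids import bin_samples
    from .conftest import truth_thickness_at_profile

    roi = clean_truth.cap_roi()
    lms = clean_truth.landmarks()
    reg = rotational_map(lms[0], lms[1], axial_map(lms))
    grid = BinGrid(length_mm=clean_truth.config.tube_length_mm)
    profiles, truth_vals = [], []
    for i in range(roi.frame_first, roi.frame_last + 1, 2):
        frame = clean_pullback.frame(i)
        lum = segment_lumen(frame)
        abl = segment_cap_abluminal(frame, roi, lum)
        prof = thickness_profile(lum, abl)
        prof.frame_index = i
        prof.z_mm = frame.z_position_mm
        tt = truth_thickness_at_profile(clean_truth, prof)
        keep = np.isfinite(tt)
        prof.thickness_um[~keep] = np.nan
        profiles.append(prof)
        truth_vals.append(tt)
    capmap = resample_cap_to_grid(profiles, reg, grid, clean_truth.config.n_alines)
    s_all = np.concatenate([np.full(p.alines.size, reg.frame_to_s(p.frame_index))
                            for p in profiles])
    th_all = np.concatenate([
        p.alines * 360.0 / clean_truth.config.n_alines
        + reg.rotation_offset(p.frame_index) for p in profiles])
    v_all = np.concatenate(truth_vals)
    truth_map, _ = bin_samples(s_all[np.isfinite(v_all)],
                               th_all[np.isfinite(v_all)],
                               v_all[np.isfinite(v_all)], grid)
    return capmap, truth_map


class TestAgreement:
    def test_identical_lists(self):
        stats = length_agreement([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert stats.bias_mm == 0.0
        assert stats.loa_mm == (0.0, 0.0)
        assert stats.pearson_r == pytest.approx(1.0)

    def test_simple_arithmetic(self):
        stats = length_agreement([10.0, 20.0], [9.0, 21.0])
        assert stats.mean_abs_diff_mm == pytest.approx(1.0)
        assert stats.bias_mm == pytest.approx(0.0)

    def test_constant_shift_moves_bias(self):
        base = np.array([10.0, 15.0, 22.0, 30.0])
        s1 = length_agreement(base, base - 0.0)
        s2 = length_agreement(base + 2.5, base)
        assert s2.bias_mm - s1.bias_mm == pytest.approx(2.5)

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(10, 30, 12)
        stats = length_agreement(a, a + rng.normal(0.4, 0.9, 12))
        lo, hi = stats.loa_mm
        assert (lo + hi) / 2 == pytest.approx(stats.bias_mm)

    def test_single_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            length_agreement([10.0], [9.0])

    def test_area_agreement_proportional_is_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert area_agreement(a, 2.7 * a) == pytest.approx(1.0)

    def test_area_agreement_antiproportional_is_minus_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert area_agreement(a, 10 - a) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            area_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
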