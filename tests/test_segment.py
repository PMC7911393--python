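"""Delineation methods: thresholds, adaptive iterations, calibration, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petmtv import (LesionBox, LiverStats, MethodSpec, PhantomConfig,
                    SphereLesion, apply_fixed_threshold,
                    apply_percent_max_threshold, calibrate_adaptive,
                    compute_liver_stats, estimate_background, generate_phantom,
                    mask_volume_cm3, percist_threshold, segment_black,
                    segment_daisne, segment_fitting, segment_lesion,
                    segment_nestle)
from petmtv.segment import blurred_sphere_profile
from petmtv.volume import SUVVolume

from conftest import make_volume


def brute_force_threshold(values, box, threshold):
    """Independent triple-loop enumeration of suprathreshold voxels."""
    count = 0
    for i in range(box.low[0], box.high[0]):
        for j in range(box.low[1], box.high[1]):
            for k in range(box.low[2], box.high[2]):
                if values[i, j, k] >= threshold:
                    count += 1
    return count


class TestLiverStats:
    def test_constant_roi(self):
        vol = make_volume(np.full((11, 11, 11), 2.0))
        stats = compute_liver_stats(vol, center_mm=(5, 5, 5), radius_mm=1.0)
        assert (stats.suv_mean, stats.suv_sd, stats.suv_max) == (2.0, 0.0, 2.0)

    def test_three_voxel_roi_hand_values(self):
        vals = np.zeros((11, 5, 5))
        vals[4, 2, 2], vals[5, 2, 2], vals[6, 2, 2] = 1.0, 2.0, 3.0
        vol = SUVVolume(values=vals, spacing=(1.0, 3.0, 3.0))
        stats = compute_liver_stats(vol, center_mm=(5.0, 6.0, 6.0), radius_mm=1.0)
        assert stats.suv_mean == pytest.approx(2.0)
        assert stats.suv_sd == pytest.approx(1.0)
        assert stats.suv_max == pytest.approx(3.0)

    def test_degenerate_rois_raise(self):
        vol = make_volume(np.ones((11, 11, 11)))
        with pytest.raises(ValueError, match="outside the grid"):
            compute_liver_stats(vol, center_mm=(0.0, 5.0, 5.0), radius_mm=3.0)
        with pytest.raises(ValueError, match="voxels"):
            compute_liver_stats(vol, center_mm=(5.2, 5.2, 5.2), radius_mm=0.1)


@pytest.mark.parametrize("mean,sd,expected", [
    (2.0, 0.3, 3.6), (0.0, 0.0, 0.0), (2.4, 0.25, 4.1)])
def test_percist_threshold_formula(mean, sd, expected):
    assert percist_threshold(LiverStats(mean, sd, max(mean, 0.1) + 3 * sd)) == \
        pytest.approx(expected)


class TestFixedThreshold:
    def test_2x2x2_enumeration(self):
        vol = make_volume(np.arange(1.0, 9.0).reshape(2, 2, 2))
        box = LesionBox(low=(0, 0, 0), high=(2, 2, 2))
        mask = apply_fixed_threshold(vol, box, 2.5)
        assert mask.n_voxels == 6 == brute_force_threshold(vol.values, box, 2.5)

    def test_threshold_zero_selects_whole_box(self):
        vol = make_volume(np.random.default_rng(0).uniform(0, 5, (4, 4, 4)))
        box = LesionBox(low=(1, 0, 0), high=(3, 4, 2))
        assert apply_fixed_threshold(vol, box, 0.0).n_voxels == box.n_voxels

    def test_threshold_above_max_gives_empty_mask(self):
        vol = make_volume(np.ones((3, 3, 3)))
        box = LesionBox(low=(0, 0, 0), high=(3, 3, 3))
        mask = apply_fixed_threshold(vol, box, 99.0)
        assert mask.n_voxels == 0

    def test_negative_threshold_raises(self):
        vol = make_volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            apply_fixed_threshold(vol, LesionBox((0, 0, 0), (3, 3, 3)), -1.0)

    @given(t1=st.floats(0, 5), t2=st.floats(0, 5))
    @settings(max_examples=30, deadline=None)
    def test_monotonicity_in_threshold(self, t1, t2):
        """mask(T1) is a superset of mask(T2) whenever T1 <= T2."""
        if t1 > t2:
            t1, t2 = t2, t1
        vol = make_volume(np.random.default_rng(1).uniform(0, 5, (6, 6, 6)))
        box = LesionBox((0, 0, 0), (6, 6, 6))
        m1 = apply_fixed_threshold(vol, box, t1).mask
        m2 = apply_fixed_threshold(vol, box, t2).mask
        assert np.all(m1 | m2 == m1)


class TestPercentMaxThreshold:
    def test_five_value_enumeration(self):
        vol = make_volume(np.array([1.0, 4.0, 4.1, 5.0, 10.0]))
        box = LesionBox((0, 0, 0), (5, 1, 1))
        mask = apply_percent_max_threshold(vol, box, 0.41)
        assert mask.threshold == pytest.approx(4.1)
        assert mask.n_voxels == 3

    def test_fraction_one_keeps_only_max(self):
        vol = make_volume(np.array([1.0, 2.0, 3.0, 3.0]))
        mask = apply_percent_max_threshold(vol, LesionBox((0, 0, 0), (4, 1, 1)), 1.0)
        assert mask.n_voxels == 2

    def test_all_zero_box_flagged(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        mask = apply_percent_max_threshold(vol, LesionBox((0, 0, 0), (3, 3, 3)))
        assert mask.n_voxels == 0 and mask.flags["all_zero_box"]

    def test_merged_vs_split_boxes_change_the_dim_lesion(self):
        """One merged box thresholds the dim lesion at 41% of the hot max."""
        vals = np.ones((20, 8, 8))
        vals[2:6, 2:6, 2:6] = 10.0    # hot lesion
        vals[12:16, 2:6, 2:6] = 3.0   # dim lesion periphery
        vals[13:15, 3:5, 3:5] = 5.0   # dim lesion core
        vol = make_volume(vals)
        merged = apply_percent_max_threshold(vol, LesionBox((0, 0, 0), (20, 8, 8)))
        split_hot = apply_percent_max_threshold(vol, LesionBox((0, 0, 0), (10, 8, 8)))
        split_dim = apply_percent_max_threshold(vol, LesionBox((10, 0, 0), (20, 8, 8)))
        assert merged.threshold == pytest.approx(4.1)
        assert split_dim.threshold == pytest.approx(2.05)
        # merged: dim periphery at 3.0 falls inside [2.05, 4.1) and is lost
        assert merged.n_voxels < split_hot.n_voxels + split_dim.n_voxels


def test_oracle_equivalence_random_volumes(rng):
    """Vectorised thresholding agrees exactly with triple-loop enumeration."""
    for _ in range(10):
        vals = rng.uniform(0, 10, (8, 8, 8))
        vol = make_volume(vals)
        box = LesionBox(tuple(rng.integers(0, 3, 3)), tuple(rng.integers(5, 9, 3)))
        t = float(rng.uniform(0, 10))
        assert apply_fixed_threshold(vol, box, t).n_voxels == \
            brute_force_threshold(vals, box, t)
        pm = apply_percent_max_threshold(vol, box, 0.41)
        assert pm.n_voxels == brute_force_threshold(vals, box, pm.threshold)


class TestBackgroundEstimate:
    def test_uniform_background(self):
        vol = make_volume(np.ones((10, 10, 10)))
        assert estimate_background(vol, LesionBox((3, 3, 3), (7, 7, 7)), 2) == 1.0

    def test_two_level_shell_mean(self):
        vals = np.ones((10, 10, 10))
        vals[:5] = 3.0  # half the shell sits at 3.0
        vol = make_volume(vals)
        box = LesionBox((4, 4, 4), (6, 6, 6))
        bg = estimate_background(vol, box, 1)
        shell_vals = []
        for i in range(3, 7):
            for j in range(3, 7):
                for k in range(3, 7):
                    if not (4 <= i < 6 and 4 <= j < 6 and 4 <= k < 6):
                        shell_vals.append(vals[i, j, k])
        assert bg == pytest.approx(np.mean(shell_vals))

    def test_edge_box_clipped_shell_still_valid(self):
        vol = make_volume(np.ones((6, 6, 6)) * 2.0)
        assert estimate_background(vol, LesionBox((0, 0, 0), (3, 3, 3)), 2) == 2.0

    def test_fully_excluded_shell_raises(self):
        vol = make_volume(np.ones((6, 6, 6)))
        box = LesionBox((2, 2, 2), (4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            estimate_background(vol, box, 1, exclusion=[LesionBox((0, 0, 0), (6, 6, 6))])


class TestNestle:
    def test_toy_box_enumeration(self):
        vals = np.array([10.0, 10.0, 9.0, 8.0, 2.0, 1.0, 1.0])
        vol = make_volume(vals)
        box = LesionBox((0, 0, 0), (7, 1, 1))
        mask = segment_nestle(vol, box, background=1.0, beta=0.15)
        assert mask.flags["i70"] == pytest.approx(9.25)   # mean{10,10,9,8}
        assert mask.threshold == pytest.approx(1.5375)
        assert mask.n_voxels == int((vals >= 1.5375).sum()) == 5

    def test_zero_background_formula(self):
        vol = make_volume(np.full((2, 2, 2), 10.0))
        mask = segment_nestle(vol, LesionBox((0, 0, 0), (2, 2, 2)), background=0.0)
        assert mask.threshold == pytest.approx(1.5)

    def test_box_max_below_background_raises(self):
        vol = make_volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="indistinguishable"):
            segment_nestle(vol, LesionBox((0, 0, 0), (3, 3, 3)), background=2.0)


class TestBlack:
    def test_uniform_lesion_fixed_point(self):
        vol = make_volume(np.full((3, 3, 3), 10.0))
        mask = segment_black(vol, LesionBox((0, 0, 0), (3, 3, 3)))
        assert mask.threshold == pytest.approx(0.307 * 10 + 0.588)
        assert mask.flags["iterations"] <= 2
        assert mask.n_voxels == 27

    def test_two_level_lesion_matches_exhaustive_fixed_point(self):
        """Brute force over the two candidate masks finds one fixed point."""
        vals = np.array([10.0] * 4 + [4.0] * 6)
        vol = make_volume(vals)
        box = LesionBox((0, 0, 0), (10, 1, 1))
        a, b = 0.307, 0.588
        candidates = {"all": vals >= 0, "top": vals >= 10}
        fixed = []
        for name, m in candidates.items():
            t = a * vals[m].mean() + b
            if np.array_equal(vals >= t, m):
                fixed.append((name, t))
        assert fixed == [("all", pytest.approx(0.307 * 6.4 + 0.588))]
        mask = segment_black(vol, box)
        assert mask.n_voxels == 10
        assert mask.threshold == pytest.approx(0.307 * 6.4 + 0.588)

    def test_threshold_escape_raises(self):
        vol = make_volume(np.full((2, 2, 2), 0.5))
        with pytest.raises(ValueError, match="escaped"):
            segment_black(vol, LesionBox((0, 0, 0), (2, 2, 2)))

    def test_max_iter_zero_returns_initial_mask_with_warning(self):
        vol = make_volume(np.array([10.0, 5.0, 1.0]))
        box = LesionBox((0, 0, 0), (3, 1, 1))
        mask = segment_black(vol, box, max_iter=0)
        assert "warning" in mask.flags
        assert mask.n_voxels == 2  # the 41% initial mask


class TestDaisne:
    def test_vanishing_background_reduces_to_fixed_fraction(self):
        vals = np.ones((8, 8, 8)) * 0.001
        vals[2:6, 2:6, 2:6] = 10.0
        vol = make_volume(vals)
        mask = segment_daisne(vol, LesionBox((0, 0, 0), (8, 8, 8)),
                              background=1e-9, m=1.0, c=0.5)
        assert mask.flags["fraction"] == pytest.approx(0.5, abs=1e-6)

    def test_lesion_equal_to_background_raises(self):
        vol = make_volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="contrast"):
            segment_daisne(vol, LesionBox((0, 0, 0), (3, 3, 3)),
                           background=1.0, m=1.0, c=0.4)

    def test_nonpositive_background_raises(self):
        vol = make_volume(np.ones((3, 3, 3)) * 5)
        with pytest.raises(ValueError, match="background"):
            segment_daisne(vol, LesionBox((0, 0, 0), (3, 3, 3)),
                           background=0.0, m=1.0, c=0.4)

    def test_calibrated_constants_recover_new_sphere(self):
        """Self-consistency: calibrate, then segment an unseen 40 mm 8:1
        sphere; recovered volume within 15% of truth."""
        m, c = calibrate_adaptive([20.0, 30.0, 50.0], [3.0, 5.0, 12.0],
                                  psf_fwhm_mm=4.4)
        spacing = (5.3, 5.3, 2.0)
        cfg = PhantomConfig(shape=(32, 32, 56), spacing=spacing, liver=None,
                            psf_fwhm_mm=4.4,
                            lesions=[SphereLesion(center_mm=(82.15, 82.15, 55.0),
                                                  radius_mm=20.0, uptake=8.0)])
        vol, truth = generate_phantom(cfg, seed=0)
        box = truth.tight_box(truth.lesions[0])
        mask = segment_daisne(vol, box, background=1.0, m=m, c=c)
        rec = mask_volume_cm3(mask, spacing)
        assert rec == pytest.approx(truth.lesions[0].true_volume_cm3, rel=0.15)


class TestCalibrateAdaptive:
    def test_two_phantoms_exact_line(self):
        m, c = calibrate_adaptive([25.0, 45.0], [4.0, 10.0], psf_fwhm_mm=4.4)
        # re-derive the two calibration points and check they sit on the line
        m2, c2 = calibrate_adaptive([25.0, 45.0], [4.0, 10.0], psf_fwhm_mm=4.4)
        assert (m, c) == (m2, c2)  # determinism
        assert np.isfinite(m) and np.isfinite(c) and 0 < c < 1

    def test_psf_zero_slope_near_zero(self):
        """Without blur any mid fraction recovers the voxelised sphere, so the
        fitted fraction is SBR-independent."""
        m, c = calibrate_adaptive([30.0, 40.0], [4.0, 8.0], psf_fwhm_mm=0.0)
        assert abs(m) < 1e-6
        assert c == pytest.approx(0.5, abs=1e-3)

    def test_degenerate_design_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_adaptive([30.0, 30.0], [8.0, 8.0], psf_fwhm_mm=4.4)

    def test_too_few_phantoms_raise(self):
        with pytest.raises(ValueError):
            calibrate_adaptive([30.0], [8.0])


class TestFitting:
    spacing = (5.3, 5.3, 2.0)

    def _forward_box(self, radius, uptake, bg, fwhm, shape=(16, 16, 40)):
        """Generate box data from the fitting method's own forward model."""
        sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
        center = tuple(self.spacing[a] * (shape[a] - 1) / 2 for a in range(3))
        axes = [self.spacing[a] * np.arange(shape[a]) for a in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        r = np.sqrt((gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2)
        vals = bg + (uptake - bg) * blurred_sphere_profile(r, radius, max(sigma, 1e-9))
        return SUVVolume(values=np.clip(vals, 0, None), spacing=self.spacing)

    def test_inverse_crime_diameter_within_one_percent(self):
        vol = self._forward_box(radius=15.0, uptake=8.0, bg=1.0, fwhm=4.4)
        box = LesionBox((0, 0, 0), vol.shape)
        res = segment_fitting(vol, box, psf_fwhm_mm=4.4)
        assert res.diameter_mm == pytest.approx(30.0, rel=0.01)

    def test_sharp_sphere_volume_within_voxel_shell(self):
        cfg = PhantomConfig(shape=(16, 16, 40), spacing=self.spacing,
                            psf_fwhm_mm=0.0, liver=None,
                            lesions=[SphereLesion(center_mm=(39.75, 39.75, 39.0),
                                                  radius_mm=15.0, uptake=8.0)])
        vol, truth = generate_phantom(cfg, seed=0)
        res = segment_fitting(vol, LesionBox((0, 0, 0), vol.shape), psf_fwhm_mm=0.0)
        r, dr = 15.0, max(self.spacing)
        shell = (4 / 3 * math.pi * ((r + dr) ** 3 - (r - dr) ** 3)) / 1000
        assert abs(res.volume_cm3 - truth.lesions[0].true_volume_cm3) < shell

    def test_flat_box_raises(self):
        vol = make_volume(np.full((5, 5, 5), 3.0), spacing=self.spacing)
        with pytest.raises(ValueError, match="flat box"):
            segment_fitting(vol, LesionBox((0, 0, 0), (5, 5, 5)))

    def test_too_small_box_raises(self):
        vol = make_volume(np.random.default_rng(0).uniform(1, 5, (3, 3, 3)))
        with pytest.raises(ValueError, match="30"):
            segment_fitting(vol, LesionBox((0, 0, 0), (3, 3, 3)))


class TestMaskVolume:
    def test_arithmetic(self):
        m = np.ones((10, 10, 1), dtype=bool)
        assert mask_volume_cm3(m, (5.3, 5.3, 2.0)) == pytest.approx(5.6180)
        assert mask_volume_cm3(np.zeros((2, 2, 2), bool), (5.3, 5.3, 2.0)) == 0.0
        assert mask_volume_cm3(np.ones((1, 1, 1), bool), (10, 10, 10)) == pytest.approx(1.0)


class TestBoxInvariance:
    """Absolute thresholds ignore the box; the relative method does not."""

    def _two_lesion_volume(self):
        vals = np.ones((24, 10, 10))
        vals[2:6, 3:7, 3:7] = 10.0   # hot lesion
        vals[14:18, 3:7, 3:7] = 5.0  # dim, isolated lesion
        return make_volume(vals)

    def test_enlarging_box_leaves_absolute_methods_unchanged(self):
        vol = self._two_lesion_volume()
        small = LesionBox((12, 1, 1), (20, 9, 9))
        large = LesionBox((10, 0, 0), (24, 10, 10))  # still excludes the hot lesion
        for t in (2.5, 3.0, 4.0):
            assert apply_fixed_threshold(vol, small, t).n_voxels == \
                apply_fixed_threshold(vol, large, t).n_voxels

    def test_percent_max_threshold_changes_when_hotter_voxel_enters(self):
        vol = self._two_lesion_volume()
        small = LesionBox((12, 1, 1), (20, 9, 9))
        large = LesionBox((0, 0, 0), (24, 10, 10))  # now captures the hot lesion
        t_small = apply_percent_max_threshold(vol, small).threshold
        t_large = apply_percent_max_threshold(vol, large).threshold
        assert t_small == pytest.approx(2.05)
        assert t_large == pytest.approx(4.1)


def test_dispatch_requires_liver_for_reference_methods():
    vol = make_volume(np.ones((4, 4, 4)) * 5)
    box = LesionBox((0, 0, 0), (4, 4, 4))
    for name in ("liver_max", "percist"):
        with pytest.raises(ValueError, match="liver"):
            segment_lesion(vol, box, MethodSpec(name=name))
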