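"""Pairwise geometry features: Dice, OVH, z-extent, 3D moment invariants."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dosecast import (compute_feature_vector, moment_invariants,
                      normalized_central_moments, ovh_curve, ovh_msd, povz,
                      ptv_dsc, ptv_length_diff)
from dosecast.features import OVHCurve, signed_distance_to_mask
from dosecast.registration import RigidTransform
from dosecast.volumes import PatientCase

from conftest import ellipsoid_mask, make_mask


class TestPtvDsc:
    def test_identical_masks_give_one(self, small_case):
        assert ptv_dsc(small_case.ptv, small_case.ptv) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((10, 10, 10)); a[:, :, :4] = 1
        b = np.zeros((10, 10, 10)); b[:, :, 6:] = 1
        assert ptv_dsc(make_mask(a), make_mask(b)) == 0.0

    def test_half_overlapping_cubes(self):
        a = np.zeros((12, 12, 12)); a[1:11, 1:11, 0:10] = 1
        b = np.zeros((12, 12, 12)); b[1:11, 1:11, 5:15] = 1  # clipped to 5..11
        b = np.zeros((12, 12, 12)); b[1:11, 1:11, 2:12] = 1
        # overlap 8 columns of 10x10, each mask 10 columns -> 2*800/2000
        assert ptv_dsc(make_mask(a), make_mask(b)) == pytest.approx(0.8)

    def test_both_empty_rejected(self):
        z = make_mask(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            ptv_dsc(z, z)


class TestZAxisFeatures:
    def test_identical_masks(self, small_case):
        assert ptv_length_diff(small_case.ptv, small_case.ptv) == 0.0
        assert povz(small_case.ptv, small_case.ptv) == 1.0

    def test_known_extents(self):
        # mask A spans z slices 0..9 (10 mm), mask B slices 0..7 (8 mm)
        a = np.zeros((12, 4, 4)); a[0:10, :, :] = 1
        b = np.zeros((12, 4, 4)); b[0:8, :, :] = 1
        assert ptv_length_diff(make_mask(a), make_mask(b)) == pytest.approx(2.0)
        # overlap 8 of (10+8)/2 -> 2*8/18
        assert povz(make_mask(a), make_mask(b)) == pytest.approx(16.0 / 18.0)

    def test_non_overlapping_extents_give_zero(self):
        a = np.zeros((12, 4, 4)); a[0:4, :, :] = 1
        b = np.zeros((12, 4, 4)); b[8:12, :, :] = 1
        assert povz(make_mask(a), make_mask(b)) == 0.0

    def test_ellipsoid_extent_matches_semiaxis(self):
        a = ellipsoid_mask((20.0, 20.0, 30.0), n=80)
        b = ellipsoid_mask((20.0, 20.0, 20.0), n=80)
        # z-extents 2c1 vs 2c2 -> difference 2|c1-c2| within one slice
        assert ptv_length_diff(a, b) == pytest.approx(20.0, abs=1.0)


class TestOvh:
    def test_oar_inside_ptv_reaches_one_at_zero(self):
        ptv = np.zeros((20, 20, 20)); ptv[4:16, 4:16, 4:16] = 1
        oar = np.zeros((20, 20, 20)); oar[8:12, 8:12, 8:12] = 1
        curve = ovh_curve(make_mask(oar), make_mask(ptv, label="PTV"))
        assert curve.fraction_at(0.0) == 1.0

    def test_single_voxel_steps_at_its_distance(self):
        ptv = np.zeros((40, 40, 40)); ptv[18:22, 18:22, 18:22] = 1
        oar = np.zeros((40, 40, 40)); oar[20, 20, 31] = 1  # 10 mm from column 21
        curve = ovh_curve(make_mask(oar), make_mask(ptv, label="PTV"))
        assert curve.fraction_at(9.9) == 0.0
        assert curve.fraction_at(10.0) == 1.0

    def test_curve_non_decreasing_for_random_blobs(self, rng):
        from scipy import ndimage
        for _ in range(3):
            a = ndimage.binary_dilation(rng.random((24, 24, 24)) > 0.97,
                                        iterations=2)
            b = ndimage.binary_dilation(rng.random((24, 24, 24)) > 0.97,
                                        iterations=2)
            if not (a.any() and b.any()):
                continue
            curve = ovh_curve(make_mask(b), make_mask(a, label="PTV"))
            assert np.all(np.diff(curve.fractions) >= 0)

    def test_ovh_msd_identity_and_shift(self):
        a = OVHCurve(np.arange(100.0), np.arange(1, 101) / 100.0)
        b = OVHCurve(np.arange(100.0) + 3.0, np.arange(1, 101) / 100.0)
        assert ovh_msd(a, a) == 0.0
        assert ovh_msd(a, b) == pytest.approx(3.0)

    def test_ovh_msd_matches_exhaustive_percentiles(self, rng):
        # toy OARs: explicit distance multisets, exhaustive 99-percentile oracle
        d1 = np.sort(rng.normal(5, 8, size=37))
        d2 = np.sort(rng.normal(2, 6, size=53))
        c1 = OVHCurve(d1, np.arange(1, 38) / 37)
        c2 = OVHCurve(d2, np.arange(1, 54) / 53)
        expected = np.mean([
            abs(d1[int(np.ceil(i / 100 * 37)) - 1]
                - d2[int(np.ceil(i / 100 * 53)) - 1])
            for i in range(1, 100)])
        assert ovh_msd(c1, c2) == pytest.approx(expected, abs=1e-12)

    def test_ovh_msd_is_pseudometric_on_samples(self, rng):
        curves = []
        for _ in range(3):
            d = np.sort(rng.normal(0, 10, size=40))
            curves.append(OVHCurve(d, np.arange(1, 41) / 40))
        a, b, c = curves
        assert ovh_msd(a, b) == pytest.approx(ovh_msd(b, a))
        assert ovh_msd(a, c) <= ovh_msd(a, b) + ovh_msd(b, c) + 1e-12

    def test_signed_distance_negative_inside(self):
        ptv = np.zeros((16, 16, 16)); ptv[4:12, 4:12, 4:12] = 1
        sd = signed_distance_to_mask(make_mask(ptv, label="PTV"))
        assert sd[8, 8, 8] < 0
        assert sd[0, 0, 0] > 0


class TestMoments:
    def test_eta000_is_one(self, small_case):
        eta = normalized_central_moments(small_case.ptv, [(0, 0, 0)])
        assert eta[(0, 0, 0)] == pytest.approx(1.0)

    def test_odd_orders_vanish_for_symmetric_mask(self):
        ball = ellipsoid_mask((15.0, 15.0, 15.0), n=40)
        eta = normalized_central_moments(ball, [(3, 0, 0), (1, 1, 1), (0, 3, 0)])
        for v in eta.values():
            assert abs(v) < 1e-3

    def test_eta200_of_unit_ball_matches_closed_form(self):
        # (4π/15) / (4π/3)^{5/3}, cross-checked by fine-grid integration
        ball = ellipsoid_mask((50.0, 50.0, 50.0), n=128)
        eta = normalized_central_moments(ball, [(2, 0, 0)])[(2, 0, 0)]
        exact = (4 * np.pi / 15) / (4 * np.pi / 3) ** (5 / 3)
        assert eta == pytest.approx(exact, rel=5e-3)

    def test_sphere_invariants_closed_forms(self):
        ball = ellipsoid_mask((50.0, 50.0, 50.0), n=128)
        eta200 = normalized_central_moments(ball, [(2, 0, 0)])[(2, 0, 0)]
        inv = moment_invariants(ball)
        assert inv.J1 == pytest.approx(3 * eta200, rel=1e-6)
        assert inv.J2 == pytest.approx(3 * eta200 ** 2, rel=1e-4)
        assert inv.J3 == pytest.approx(eta200 ** 3, rel=1e-4)

    def test_rotation_invariance(self):
        base = ellipsoid_mask((24, 18, 12), bump=0.5)
        R = Rotation.from_rotvec(np.deg2rad(30) * np.array([1, 1, 1])
                                 / np.sqrt(3)).as_matrix()
        rot = ellipsoid_mask((24, 18, 12), rotation=R, bump=0.5)
        np.testing.assert_allclose(moment_invariants(rot).as_array(),
                                   moment_invariants(base).as_array(),
                                   rtol=0.02)

    def test_scale_invariance(self):
        base = ellipsoid_mask((24, 18, 12), bump=0.5)
        big = ellipsoid_mask((36, 27, 18), bump=0.5, n=120)
        np.testing.assert_allclose(moment_invariants(big).as_array(),
                                   moment_invariants(base).as_array(),
                                   rtol=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalized_central_moments(make_mask(np.zeros((4, 4, 4))),
                                       [(2, 0, 0)])


class TestFeatureVector:
    def test_self_pair_attains_minima(self, small_case):
        fv = compute_feature_vector(small_case, small_case)
        assert fv.image_msd == 0.0
        assert fv.ptv_dsc_recip == 1.0
        assert fv.povz_recip == 1.0
        assert fv.ovh_msd_lung == 0.0
        assert fv.ovh_msd_heart == 0.0
        assert fv.ptv_length_diff == 0.0
        for name in ("J1_diff", "J2_diff", "J3_diff", "B3_diff", "B4_diff"):
            assert getattr(fv, name) == 0.0

    def test_all_entries_finite_and_nonnegative(self, small_pair):
        fixed, floating = small_pair
        fv = compute_feature_vector(fixed, floating)
        arr = fv.as_array()
        assert np.all(np.isfinite(arr)) and np.all(arr >= 0)

    def test_pure_z_shift_leaves_shape_invariants_unchanged(self, small_case):
        sz = small_case.image.spacing[2]
        shifted_structs = {}
        for label, m in small_case.structures.items():
            arr = np.roll(m.voxels, 4, axis=0)
            arr[:4] = 0
            shifted_structs[label] = make_mask(arr, m.spacing, m.origin,
                                               label=label)
        shifted = PatientCase(id="shifted", image=small_case.image,
                              structures=shifted_structs, dose=small_case.dose)
        fv = compute_feature_vector(small_case, shifted)
        # translation leaves the 3DMI shape descriptors untouched
        for name in ("J1_diff", "J2_diff", "J3_diff", "B3_diff", "B4_diff"):
            assert getattr(fv, name) == pytest.approx(0.0, abs=1e-6)
        assert fv.ptv_dsc_recip > 1.0
        assert fv.povz_recip > 1.0

    def test_entries_match_individual_ops(self, small_pair):
        from dosecast import msd_metric, resample_to_reference
        fixed, floating = small_pair
        rigid = RigidTransform.identity()
        fv = compute_feature_vector(fixed, floating, rigid)
        a_ptv = resample_to_reference(floating.ptv, fixed.image, "nearest")
        assert fv.ptv_dsc_recip == pytest.approx(
            1.0 / ptv_dsc(fixed.ptv, a_ptv))
        assert fv.ptv_length_diff == pytest.approx(
            ptv_length_diff(fixed.ptv, a_ptv))
        assert fv.povz_recip == pytest.approx(1.0 / povz(fixed.ptv, a_ptv))
        inv_f = moment_invariants(fixed.ptv)
        inv_m = moment_invariants(floating.ptv)
        assert fv.J1_diff == pytest.approx(abs(inv_f.J1 - inv_m.J1))
        img = resample_to_reference(floating.image, fixed.image, "linear")
        assert fv.image_msd == pytest.approx(msd_metric(fixed.image, img))

    def test_missing_structure_named_in_error(self, small_case):
        reduced = {k: v for k, v in small_case.structures.items()
                   if k != "heart"}
        partial = PatientCase(id="partial", image=small_case.image,
                              structures=reduced, dose=small_case.dose)
        with pytest.raises(ValueError, match="heart"):
            compute_feature_vector(small_case, partial)

    def test_reciprocal_guard_caps_zero_overlap(self):
        a = np.zeros((20, 8, 8)); a[2:6, 2:6, 2:6] = 1
        b = np.zeros((20, 8, 8)); b[12:16, 2:6, 2:6] = 1
        from dosecast.features import _guarded_reciprocal
        assert _guarded_reciprocal(ptv_dsc(make_mask(a), make_mask(b)),
                                   1e3) == 1e3
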