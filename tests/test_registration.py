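"""Rigid, Demons and PTV-constrained registration stages and dose warping."""

import numpy as np
import pytest
import SimpleITK as sitk

from dosecast import (DoseVolume, ImageVolume, MaskVolume, msd_metric,
                      register_rigid, register_demons, register_mask_constraint,
                      resample_to_reference, warp_dose)
from dosecast.registration import (DisplacementField, RigidTransform,
                                   TransformChain, _dice)

from conftest import ellipsoid_mask


class TestMsdMetric:
    def test_identical_volumes_give_zero(self, small_case):
        assert msd_metric(small_case.image, small_case.image) == 0.0

    def test_constant_offset_gives_square(self, small_case):
        shifted = small_case.image.with_voxels(small_case.image.voxels + 4.0)
        assert msd_metric(small_case.image, shifted) == pytest.approx(16.0)

    def test_matches_brute_force_loop(self, rng):
        a = ImageVolume(rng.random((2, 2, 2)))
        b = ImageVolume(rng.random((2, 2, 2)))
        brute = np.mean([(a.voxels[i] - b.voxels[i]) ** 2
                         for i in np.ndindex(2, 2, 2)])
        assert msd_metric(a, b) == pytest.approx(brute)

    def test_grid_mismatch_rejected(self):
        a = ImageVolume(np.zeros((4, 4, 4)))
        b = ImageVolume(np.zeros((4, 4, 4)), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            msd_metric(a, b)


class TestRigid:
    def test_constant_image_rejected(self):
        flat = ImageVolume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="constant"):
            register_rigid(flat, flat)

    def test_self_registration_near_identity(self, small_case):
        tx = register_rigid(small_case.image, small_case.image)
        voxel = min(small_case.image.spacing)
        assert np.linalg.norm(tx.translation) < 0.5 * voxel
        assert np.linalg.norm(tx.versor) < np.sin(np.deg2rad(0.5) / 2)
        assert tx.scale == pytest.approx(1.0, abs=0.01)

    def test_known_translation_recovered(self, small_case):
        T = sitk.Similarity3DTransform()
        T.SetTranslation((10.0, -6.0, 4.0))
        floating = resample_to_reference(small_case.image, small_case.image,
                                         "linear", transform=T,
                                         default_value=-1000.0)
        tx = register_rigid(small_case.image, floating)
        # floating(x) = fixed(T(x)), so registration recovers T^{-1}
        Ti = T.GetInverse()
        probes = [(0.0, 0.0, 0.0), (40.0, -30.0, 20.0), (-50.0, 10.0, -60.0)]
        errs = [np.linalg.norm(np.array(tx.transform_point(p))
                               - np.array(Ti.TransformPoint(p)))
                for p in probes]
        assert max(errs) < max(small_case.image.spacing)  # within one voxel

    def test_known_scale_recovered(self, small_case):
        S = sitk.Similarity3DTransform()
        S.SetScale(1.1)
        floating = resample_to_reference(small_case.image, small_case.image,
                                         "linear", transform=S,
                                         default_value=-1000.0)
        tx = register_rigid(small_case.image, floating)
        assert tx.scale == pytest.approx(1.0 / 1.1, rel=0.02)

    def test_cross_phantom_does_not_worsen_msd(self, small_pair):
        fixed, floating = small_pair
        tx = register_rigid(fixed.image, floating.image)
        bg = float(floating.image.voxels.min())
        warped = resample_to_reference(floating.image, fixed.image, "linear",
                                       transform=tx.to_sitk(), default_value=bg)
        baseline = resample_to_reference(floating.image, fixed.image, "linear",
                                         default_value=bg)
        assert msd_metric(fixed.image, warped) <= msd_metric(fixed.image, baseline)


class TestDemons:
    def test_self_registration_field_near_zero(self, small_case):
        field = register_demons(small_case.image, small_case.image)
        assert field.magnitude().max() < 0.5 * min(small_case.image.spacing)

    def test_improves_msd_over_rigid_only(self, small_pair):
        fixed, floating = small_pair
        rigid = register_rigid(fixed.image, floating.image)
        bg = float(floating.image.voxels.min())
        moving = resample_to_reference(floating.image, fixed.image, "linear",
                                       transform=rigid.to_sitk(),
                                       default_value=bg)
        field = register_demons(fixed.image, floating.image, rigid)
        warped = resample_to_reference(moving, fixed.image, "linear",
                                       transform=field.to_transform(),
                                       default_value=bg)
        assert msd_metric(fixed.image, warped) < msd_metric(fixed.image, moving)

    def test_recovers_smooth_sinusoidal_warp(self, small_case):
        img = small_case.image
        nz, ny, nx = img.shape
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in (nz, ny, nx)),
                                 indexing="ij")
        amp = 5.0  # mm
        vec = np.stack([amp * np.sin(2 * np.pi * zz / nz),
                        amp * np.sin(2 * np.pi * xx / nx),
                        np.zeros_like(xx, dtype=float)], axis=-1)
        known = DisplacementField(vec, img.spacing, img.origin, img.direction)
        warped = resample_to_reference(img, img, "linear",
                                       transform=known.to_transform(),
                                       default_value=float(img.voxels.min()))
        rec = register_demons(img, ImageVolume(warped.voxels, img.spacing,
                                               img.origin, img.direction))
        # recovered field composes to identity with the known one near the PTV
        err = np.linalg.norm(rec.vectors + vec, axis=-1)
        from scipy import ndimage
        near_ptv = ndimage.binary_dilation(small_case.ptv.voxels > 0,
                                           iterations=3)
        assert err[near_ptv].mean() < 2.0  # mm

    def test_non_finite_field_rejected(self, small_case):
        with pytest.raises(ValueError, match="finite"):
            DisplacementField(np.full(small_case.image.shape + (3,), np.nan),
                              small_case.image.spacing, small_case.image.origin,
                              small_case.image.direction)


class TestMaskConstraint:
    def test_identical_masks_near_zero_field(self, small_case):
        field = register_mask_constraint(small_case.ptv, small_case.ptv)
        assert field.magnitude().max() < 0.5 * min(small_case.ptv.spacing)

    def test_empty_mask_rejected(self, small_case):
        empty = MaskVolume(np.zeros(small_case.ptv.shape, np.uint8),
                           small_case.ptv.spacing, small_case.ptv.origin,
                           label="PTV")
        with pytest.raises(ValueError, match="non-empty"):
            register_mask_constraint(small_case.ptv, empty)

    def test_offset_spheres_improve_dice(self):
        a = ellipsoid_mask((40, 40, 40), spacing=4.0, n=48, label="PTV")
        b = ellipsoid_mask((40, 40, 40), center=(6.0, 0, 0), spacing=4.0,
                           n=48, label="PTV")
        field = register_mask_constraint(a, b)
        warped = resample_to_reference(b, a, "nearest",
                                       transform=field.to_transform())
        assert _dice(a.voxels, warped.voxels) > _dice(a.voxels, b.voxels)

    def test_scaled_sphere_reaches_high_dice(self):
        a = ellipsoid_mask((40, 40, 40), spacing=4.0, n=48, label="PTV")
        s = ellipsoid_mask((48, 48, 48), spacing=4.0, n=48, label="PTV")
        field = register_mask_constraint(a, s)
        warped = resample_to_reference(s, a, "nearest",
                                       transform=field.to_transform())
        assert _dice(a.voxels, warped.voxels) >= 0.95


class TestDoseWarp:
    def test_identity_chain_equals_resample(self, small_pair):
        fixed, floating = small_pair
        out = warp_dose(floating.dose, TransformChain(), fixed.image)
        plain = resample_to_reference(floating.dose, fixed.image, "linear")
        np.testing.assert_allclose(out.voxels, plain.voxels)
        assert out.prescription == floating.dose.prescription

    def test_uniform_dose_preserved_in_interior(self, small_case):
        rx = 5000.0
        uniform = DoseVolume(np.full(small_case.image.shape, rx),
                             small_case.image.spacing, small_case.image.origin,
                             prescription=rx)
        tx = RigidTransform(versor=(0, 0, 0), translation=(3.0, -2.0, 1.0),
                            scale=1.0)
        out = warp_dose(uniform, TransformChain(rigid=tx), small_case.image)
        np.testing.assert_allclose(out.voxels[4:-4, 4:-4, 4:-4], rx)

    def test_translation_relocates_step_exactly(self, small_case):
        sx = small_case.image.spacing[0]
        step = np.zeros(small_case.image.shape)
        step[:, :, 32:] = 100.0
        dose = DoseVolume(step, small_case.image.spacing,
                          small_case.image.origin, prescription=5000.0)
        tx = RigidTransform(versor=(0, 0, 0), translation=(2 * sx, 0, 0),
                            scale=1.0)
        out = warp_dose(dose, TransformChain(rigid=tx), small_case.image)
        np.testing.assert_allclose(out.voxels[:, :, :30],
                                   step[:, :, 2:32], atol=1e-9)

    def test_warping_is_linear_in_dose(self, small_pair, rng):
        fixed, floating = small_pair
        tx = RigidTransform(versor=(0.02, 0.01, -0.015),
                            translation=(5.0, -3.0, 2.0), scale=1.02)
        chain = TransformChain(rigid=tx)
        d1 = DoseVolume(rng.random(floating.image.shape) * 100,
                        floating.image.spacing, floating.image.origin)
        d2 = DoseVolume(rng.random(floating.image.shape) * 100,
                        floating.image.spacing, floating.image.origin)
        mix = DoseVolume(0.3 * d1.voxels + 0.7 * d2.voxels,
                         floating.image.spacing, floating.image.origin)
        w1 = warp_dose(d1, chain, fixed.image)
        w2 = warp_dose(d2, chain, fixed.image)
        wm = warp_dose(mix, chain, fixed.image)
        np.testing.assert_allclose(wm.voxels,
                                   0.3 * w1.voxels + 0.7 * w2.voxels,
                                   atol=1e-8)
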