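"""Three-stage inter-patient registration and dose warping.

The registration pipeline maps an atlas case (floating) onto a new patient's
grid (fixed) in three stages:

1. ``f_R`` — a 7-parameter similarity transform (three rotation angles, a 3-vector
   translation, one isotropic scale), optimised on the mean squared intensity
   deviation (MSD) with a regular-step gradient descent over a multi-resolution
   pyramid.
2. ``f_D`` — Demons deformable refinement (symmetric forces, Gaussian field
   smoothing, multi-resolution) of the rigidly aligned image.
3. ``f_P`` — a further Demons registration of the binary PTV masks (Gaussian
   pre-smoothed so step images have usable gradients), concentrating accuracy on
   the target region that dominates plan optimisation.

The composed mapping is ``f_P(f_D(f_R(·)))``; an atlas dose is carried onto the
new grid through the same composition with trilinear interpolation.

Each stage is guarded to be non-worsening in its own objective: if the optimiser
returns a transform that increases MSD (or decreases PTV Dice for ``f_P``), the
stage falls back to identity with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .volumes import DoseVolume, ImageVolume, MaskVolume, resample_to_reference

__all__ = [
    "RegistrationConfig",
    "RigidTransform",
    "DisplacementField",
    "TransformChain",
    "msd_metric",
    "register_rigid",
    "register_demons",
    "register_mask_constraint",
    "build_chain",
    "warp_dose",
]


@dataclass
class RegistrationConfig:
    """Knobs for the three registration stages.

    Iteration counts are per pyramid level, coarse to fine; sigmas for the Demons
    field smoothing are in voxels.  Defaults favour robustness at desk-scale
    grids (~100³ voxels); registration itself is deterministic (full-image MSD,
    no metric sampling), the seed is carried for config completeness.
    """

    rigid_shrink_factors: Sequence[int] = (4, 2, 1)
    rigid_smoothing_sigmas: Sequence[float] = (2.0, 1.0, 0.0)
    rigid_iterations: int = 200
    rigid_learning_rate: float = 1.0
    rigid_min_step: float = 1e-4
    demons_shrink_factors: Sequence[int] = (1,)
    demons_iterations: Sequence[int] = (60,)
    demons_smoothing_sigma: float = 1.5
    mask_shrink_factors: Sequence[int] = (1,)
    mask_iterations: Sequence[int] = (50,)
    mask_smoothing_sigma: float = 1.5
    mask_presmooth_vox: float = 1.0
    seed: int = 0


@dataclass
class RigidTransform:
    """Similarity transform ``f_R``: rotation versor, translation (mm), isotropic scale."""

    versor: tuple
    translation: tuple
    scale: float
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    def to_sitk(self) -> sitk.Similarity3DTransform:
        t = sitk.Similarity3DTransform()
        t.SetCenter(self.center)
        # parameter layout: versor (3), translation (3), scale (1)
        t.SetParameters(tuple(self.versor) + tuple(self.translation) + (self.scale,))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Similarity3DTransform) -> "RigidTransform":
        p = t.GetParameters()
        return cls(versor=tuple(p[0:3]), translation=tuple(p[3:6]), scale=float(p[6]),
                   center=tuple(t.GetCenter()))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(versor=(0.0, 0.0, 0.0), translation=(0.0, 0.0, 0.0), scale=1.0)

    def transform_point(self, p):
        return self.to_sitk().TransformPoint(tuple(float(v) for v in p))

    def to_dict(self):
        return {"versor": list(self.versor), "translation": list(self.translation),
                "scale": self.scale, "center": list(self.center)}

    @classmethod
    def from_dict(cls, d):
        return cls(versor=tuple(d["versor"]), translation=tuple(d["translation"]),
                   scale=float(d["scale"]), center=tuple(d["center"]))


@dataclass
class DisplacementField:
    """Dense displacement field (mm) on the fixed-image grid.

    ``vectors`` has shape ``(nz, ny, nx, 3)`` with (x, y, z) world components,
    matching SimpleITK's array layout for vector images.
    """

    vectors: np.ndarray
    spacing: tuple
    origin: tuple
    direction: tuple

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (nz, ny, nx, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field must be finite everywhere")

    @classmethod
    def zero(cls, reference: ImageVolume) -> "DisplacementField":
        return cls(np.zeros(reference.shape + (3,)), reference.spacing,
                   reference.origin, reference.direction)

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "DisplacementField":
        return cls(sitk.GetArrayFromImage(img), img.GetSpacing(), img.GetOrigin(),
                   img.GetDirection())

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.vectors, isVector=True)
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return sitk.Cast(img, sitk.sitkVectorFloat64)

    def to_transform(self) -> sitk.DisplacementFieldTransform:
        # DisplacementFieldTransform takes ownership of the image; always hand
        # it a fresh copy so this object stays reusable.
        return sitk.DisplacementFieldTransform(self.to_sitk())

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


@dataclass
class TransformChain:
    """The composed atlas→patient mapping ``f_P(f_D(f_R(·)))``.

    Any stage may be None (identity).  ``to_sitk`` builds the composite resampling
    transform: a point on the fixed grid passes through ``f_P``'s field, then
    ``f_D``'s, then ``f_R``, which is exactly how the staged pipeline sampled the
    floating image.
    """

    rigid: RigidTransform | None = None
    demons: DisplacementField | None = None
    ptv: DisplacementField | None = None

    def to_sitk(self) -> sitk.Transform:
        comp = sitk.CompositeTransform(3)
        # composite applies the *last added* transform to the point first
        if self.rigid is not None:
            comp.AddTransform(self.rigid.to_sitk())
        if self.demons is not None:
            comp.AddTransform(self.demons.to_transform())
        if self.ptv is not None:
            comp.AddTransform(self.ptv.to_transform())
        return comp

    def warp(self, volume, reference: ImageVolume, interp: str = "linear"):
        return resample_to_reference(volume, reference, interp=interp,
                                     transform=self.to_sitk())


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def msd_metric(a: ImageVolume, b: ImageVolume) -> float:
    """Mean squared intensity deviation between two volumes on one grid."""
    if not a.same_grid(b):
        raise ValueError("msd_metric requires volumes on the same grid")
    diff = a.voxels.astype(np.float64) - b.voxels.astype(np.float64)
    return float(np.mean(diff * diff))


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a > 0
    b = b > 0
    s = a.sum() + b.sum()
    if s == 0:
        raise ValueError("both masks empty")
    return 2.0 * np.logical_and(a, b).sum() / s


# ---------------------------------------------------------------------------
# Stage 1: rigid (similarity) registration
# ---------------------------------------------------------------------------

def register_rigid(fixed: ImageVolume, floating: ImageVolume,
                   config: RegistrationConfig | None = None) -> RigidTransform:
    """Estimate the 7-parameter similarity transform minimising image MSD.

    Returns the transform mapping fixed-grid points into floating space (the
    resampling convention).  Guaranteed non-worsening: if the optimised result
    has higher MSD than no transform at all, identity is returned with a warning.
    """
    config = config or RegistrationConfig()
    for name, vol in (("fixed", fixed), ("floating", floating)):
        if np.ptp(vol.voxels) == 0:
            raise ValueError(f"{name} image is constant; rigid registration undefined")

    f_img = fixed.to_sitk(dtype=np.float64)
    m_img = floating.to_sitk(dtype=np.float64)
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Similarity3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=config.rigid_learning_rate,
        minStep=config.rigid_min_step,
        numberOfIterations=config.rigid_iterations,
        gradientMagnitudeTolerance=1e-7)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(config.rigid_shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(config.rigid_smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(init, inPlace=False)
    try:
        result = reg.Execute(f_img, m_img)
    except RuntimeError as err:  # pragma: no cover - optimizer blow-up
        warnings.warn(f"rigid registration failed ({err}); returning identity")
        return RigidTransform.identity()

    final = result.Downcast()
    if isinstance(final, sitk.CompositeTransform):
        final = final.GetNthTransform(final.GetNumberOfTransforms() - 1).Downcast()
    tx = RigidTransform.from_sitk(final)
    # out-of-grid fill must match the background intensity, otherwise any
    # nonzero transform is penalised at the borders against CT air
    bg = float(floating.voxels.min())
    warped = resample_to_reference(floating, fixed, "linear",
                                   transform=tx.to_sitk(), default_value=bg)
    baseline = resample_to_reference(floating, fixed, "linear", default_value=bg)
    if msd_metric(fixed, warped) > msd_metric(fixed, baseline):
        warnings.warn("rigid registration worsened MSD; falling back to identity")
        return RigidTransform.identity()
    return tx


# ---------------------------------------------------------------------------
# Stage 2/3: Demons
# ---------------------------------------------------------------------------

def _shrink(img: sitk.Image, factor: int, sigma_vox: float) -> sitk.Image:
    if factor == 1:
        return img
    if sigma_vox > 0:
        sigma_phys = [sigma_vox * s for s in img.GetSpacing()]
        img = sitk.SmoothingRecursiveGaussian(img, sigma_phys)
    return sitk.Shrink(img, [factor] * 3)


def _multiscale_demons(fixed: sitk.Image, moving: sitk.Image,
                       shrink_factors: Sequence[int],
                       iterations: Sequence[int],
                       smoothing_sigma: float) -> sitk.Image:
    """Symmetric-forces Demons over an image pyramid; returns the field image."""
    if len(shrink_factors) != len(iterations):
        raise ValueError("shrink_factors and iterations must align")
    field = None
    for factor, iters in zip(shrink_factors, iterations):
        f_l = _shrink(fixed, factor, factor / 2.0)
        m_l = _shrink(moving, factor, factor / 2.0)
        dem = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        dem.SetNumberOfIterations(int(iters))
        dem.SetSmoothDisplacementField(True)
        dem.SetStandardDeviations(smoothing_sigma)
        if field is None:
            field = sitk.Image(f_l.GetSize(), sitk.sitkVectorFloat64)
            field.CopyInformation(f_l)
        else:
            field = sitk.Resample(field, f_l, sitk.Transform(), sitk.sitkLinear)
            field = sitk.Cast(field, sitk.sitkVectorFloat64)
        field = dem.Execute(f_l, m_l, field)
    if shrink_factors[-1] != 1:
        field = sitk.Resample(field, fixed, sitk.Transform(), sitk.sitkLinear)
    field = sitk.Cast(field, sitk.sitkVectorFloat64)
    return field


def register_demons(fixed: ImageVolume, floating: ImageVolume,
                    init: RigidTransform | None = None,
                    config: RegistrationConfig | None = None) -> DisplacementField:
    """Demons refinement ``f_D`` after rigid pre-alignment ``init``.

    The floating image is first resampled through ``init`` onto the fixed grid,
    so the returned field lives on the fixed grid and composes as
    ``f_D ∘ f_R``.  Non-worsening in MSD by construction (identity fallback).
    """
    config = config or RegistrationConfig()
    init = init or RigidTransform.identity()
    bg = float(floating.voxels.min())
    moving = resample_to_reference(floating, fixed, "linear",
                                   transform=init.to_sitk(), default_value=bg)
    field_img = _multiscale_demons(
        fixed.to_sitk(dtype=np.float64), moving.to_sitk(dtype=np.float64),
        config.demons_shrink_factors, config.demons_iterations,
        config.demons_smoothing_sigma)
    field = DisplacementField.from_sitk(field_img)
    warped = resample_to_reference(moving, fixed, "linear",
                                   transform=field.to_transform(), default_value=bg)
    if msd_metric(fixed, warped) > msd_metric(fixed, moving):
        warnings.warn("demons stage worsened MSD; returning zero field")
        return DisplacementField.zero(fixed)
    return field


def register_mask_constraint(fixed_ptv: MaskVolume, floating_ptv_warped: MaskVolume,
                             config: RegistrationConfig | None = None
                             ) -> DisplacementField:
    """PTV-constrained refinement ``f_P``: Demons on the binary PTV masks.

    Both masks are Gaussian pre-smoothed (``mask_presmooth_vox`` voxels) so that
    the step images have gradients the Demons forces can use.  Non-worsening in
    PTV Dice (identity fallback).
    """
    config = config or RegistrationConfig()
    if fixed_ptv.empty or floating_ptv_warped.empty:
        raise ValueError("PTV masks must be non-empty for the constraint stage")
    if not fixed_ptv.same_grid(floating_ptv_warped):
        raise ValueError("PTV masks must share a grid")

    sig = [config.mask_presmooth_vox * s for s in fixed_ptv.spacing]
    f_img = sitk.SmoothingRecursiveGaussian(fixed_ptv.to_sitk(dtype=np.float64), sig)
    m_img = sitk.SmoothingRecursiveGaussian(
        floating_ptv_warped.to_sitk(dtype=np.float64), sig)
    field_img = _multiscale_demons(
        f_img, m_img, config.mask_shrink_factors, config.mask_iterations,
        config.mask_smoothing_sigma)
    field = DisplacementField.from_sitk(field_img)

    warped = resample_to_reference(floating_ptv_warped, fixed_ptv, "nearest",
                                   transform=field.to_transform())
    ref_grid = ImageVolume(np.zeros(fixed_ptv.shape), fixed_ptv.spacing,
                           fixed_ptv.origin, fixed_ptv.direction)
    before = _dice(fixed_ptv.voxels, floating_ptv_warped.voxels)
    after = _dice(fixed_ptv.voxels, warped.voxels)
    if after < before:
        warnings.warn("PTV-constraint stage reduced mask Dice; returning zero field")
        return DisplacementField.zero(ref_grid)
    return field


# ---------------------------------------------------------------------------
# Full chain and dose warping
# ---------------------------------------------------------------------------

def build_chain(fixed_case, floating_case,
                config: RegistrationConfig | None = None,
                rigid: RigidTransform | None = None) -> TransformChain:
    """Run all three stages for an atlas (floating) → new patient (fixed) pair.

    A precomputed ``rigid`` stage (e.g. from similarity scoring) is reused when
    given, avoiding a second rigid optimisation.
    """
    config = config or RegistrationConfig()
    if rigid is None:
        rigid = register_rigid(fixed_case.image, floating_case.image, config)
    demons = register_demons(fixed_case.image, floating_case.image, rigid, config)
    partial = TransformChain(rigid=rigid, demons=demons)
    ptv_warped = partial.warp(floating_case.ptv, fixed_case.image, interp="nearest")
    if ptv_warped.empty:
        # rigid+demons pushed the PTV off-grid; fall back to mask-only constraint
        ptv_warped = resample_to_reference(floating_case.ptv, fixed_case.image,
                                           "nearest")
    ptv_field = register_mask_constraint(fixed_case.ptv, ptv_warped, config)
    return TransformChain(rigid=rigid, demons=demons, ptv=ptv_field)


def warp_dose(atlas_dose: DoseVolume, chain: TransformChain,
              reference: ImageVolume) -> DoseVolume:
    """Carry an atlas dose onto the new grid through ``f_P(f_D(f_R(D_atlas)))``.

    Trilinear interpolation; prescription metadata is preserved.
    """
    out = chain.warp(atlas_dose, reference, interp="linear")
    return out
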