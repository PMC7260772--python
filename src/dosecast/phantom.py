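"""Synthetic thorax phantoms: image, five structures and a VMAT-like dose.

Each phantom emulates a left-breast radiotherapy case on a desk-scale grid:
an elliptic-cylinder body with a left-anterior breast bulge, two lung
ellipsoids (ipsilateral = left), a heart between them, a posterior spinal cord,
and a CT-like intensity image (air / lung / soft-tissue / bone bands plus
noise).  The clinical target volume (CTV) is the breast bulge; the planning
target volume (PTV) adds a 10-mm isotropic margin and is clipped 5 mm inside
the skin surface.  The prescription is 5000 cGy.

The dose is analytic morphology, not beam physics: prescription-level dose
(with a smooth ±noise band) inside the PTV, a Gaussian falloff with the signed
distance outside it, and a low-dose tangential corridor through the
ipsilateral lung at the PTV's head–foot/anterior position.  That reproduces
the qualitative behaviour the evaluation stack measures — steep dose gradient
at the PTV margin, moderate ipsilateral-lung dose, near-flat low spinal-cord
dose — which is what makes the full pipeline testable without clinical data.

All randomness is driven by the per-case seed; the same parameters generate
bit-identical cases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import (DoseVolume, ImageVolume, MaskVolume, PatientCase,
                      write_case)

__all__ = ["PhantomParams", "generate_case", "analytic_dose", "generate_cohort"]


@dataclass
class PhantomParams:
    """Geometry, dose and noise knobs of one phantom case (lengths in mm)."""

    shape: tuple = (64, 96, 96)          # (nz, ny, nx) voxels
    spacing: tuple = (3.0, 3.0, 3.0)     # (sx, sy, sz) mm
    body_semiaxes: tuple = (130.0, 95.0)         # (x, y) of the body cylinder
    breast_semiaxes: tuple = (55.0, 45.0, 50.0)  # breast/CTV ellipsoid (x, y, z)
    breast_angle_deg: float = 45.0       # anterior-left azimuth of the bulge
    breast_z_offset: float = 0.0
    lung_semiaxes: tuple = (42.0, 58.0, 80.0)
    heart_semiaxes: tuple = (54.0, 46.0, 54.0)
    cord_radius: float = 6.0
    ctv_to_ptv_margin: float = 10.0
    skin_clip: float = 5.0
    dose_sigma: float = 12.0             # Gaussian falloff scale outside the PTV
    corridor_amplitude: float = 0.15     # tangential corridor, fraction of Rx
    prescription: float = 5000.0         # cGy
    noise_level: float = 0.02            # relative dose noise inside the PTV
    image_noise_hu: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.ctv_to_ptv_margin < 0 or self.skin_clip < 0:
            raise ValueError("margins must be non-negative")
        if self.dose_sigma <= 0:
            raise ValueError("dose falloff sigma must be positive")


def _world_grids(params: PhantomParams):
    """Centered world-coordinate arrays (z, y, x order), mm."""
    nz, ny, nx = params.shape
    sx, sy, sz = params.spacing
    z = (np.arange(nz) - (nz - 1) / 2) * sz
    y = (np.arange(ny) - (ny - 1) / 2) * sy
    x = (np.arange(nx) - (nx - 1) / 2) * sx
    return np.meshgrid(z, y, x, indexing="ij")


def _grid_meta(params: PhantomParams):
    nz, ny, nx = params.shape
    sx, sy, sz = params.spacing
    origin = (-(nx - 1) / 2 * sx, -(ny - 1) / 2 * sy, -(nz - 1) / 2 * sz)
    return params.spacing, origin


def _smooth_noise(shape, rng, sigma_vox=4.0):
    """Zero-mean, unit-amplitude smooth random field."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma_vox)
    return sm / (np.abs(sm).max() + 1e-12)


def _mm_dilate(mask: np.ndarray, dist_mm: float, sampling) -> np.ndarray:
    if dist_mm <= 0:
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return d <= dist_mm


def generate_case(params: PhantomParams, case_id: str = "phantom") -> PatientCase:
    """Rasterise one phantom case (image + 6 structures + dose)."""
    rng = np.random.default_rng(params.seed)
    zz, yy, xx = _world_grids(params)
    spacing, origin = _grid_meta(params)
    sampling = params.spacing[::-1]  # (z, y, x)
    nz = params.shape[0]
    z_span = (nz - 1) / 2 * params.spacing[2]

    ax, ay = params.body_semiaxes
    trunk = ((xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0) \
        & (np.abs(zz) <= z_span - 2 * params.spacing[2])

    # breast bulge centered on the left-anterior body surface (LPS: +x left, -y anterior)
    th = np.deg2rad(params.breast_angle_deg)
    bx, by = ax * np.cos(th), -ay * np.sin(th)
    bz = params.breast_z_offset
    ba, bb, bc = params.breast_semiaxes
    wobble = 1.0 + 0.06 * np.sin(2 * np.pi * (zz - bz) / 160.0
                                 + 2 * np.pi * rng.random())
    breast = (((xx - bx) / (ba * wobble)) ** 2 + ((yy - by) / (bb * wobble)) ** 2
              + ((zz - bz) / bc) ** 2) <= 1.0
    breast &= np.abs(zz) <= z_span - 2 * params.spacing[2]
    body = trunk | breast
    ctv = breast

    la, lb, lc = params.lung_semiaxes
    lung_l = (((xx - 58.0) / la) ** 2 + ((yy - 0.0) / lb) ** 2
              + (zz / lc) ** 2) <= 1.0
    lung_r = (((xx + 58.0) / la) ** 2 + ((yy - 0.0) / lb) ** 2
              + (zz / lc) ** 2) <= 1.0
    lung_l &= trunk
    lung_r &= trunk
    whole_lung = lung_l | lung_r

    ha, hb, hc = params.heart_semiaxes
    heart = (((xx - 12.0) / ha) ** 2 + ((yy + 8.0) / hb) ** 2
             + ((zz + 20.0) / hc) ** 2) <= 1.0
    heart &= trunk & ~whole_lung

    cord = (xx ** 2 + (yy - 72.0) ** 2) <= params.cord_radius ** 2
    cord &= trunk
    spine = (xx ** 2 + (yy - 72.0) ** 2) <= (params.cord_radius + 9.0) ** 2
    spine &= trunk

    # PTV: CTV + margin, clipped to stay ≥ skin_clip inside the body surface
    ptv = _mm_dilate(ctv, params.ctv_to_ptv_margin, sampling)
    depth = ndimage.distance_transform_edt(body, sampling=sampling)
    ptv &= depth >= params.skin_clip
    if not ptv.any():
        raise ValueError("PTV empty after skin clipping; enlarge the breast bulge")

    # CT-like intensities
    img = np.full(params.shape, -1000.0)
    img[body] = 40.0
    img[whole_lung] = -700.0
    img[spine & ~cord] = 350.0
    img[cord] = 30.0
    img = ndimage.gaussian_filter(img, 0.7)
    img += params.image_noise_hu * rng.standard_normal(params.shape)

    def mk(label, arr):
        return MaskVolume(arr.astype(np.uint8), spacing, origin, label=label)

    image = ImageVolume(img, spacing, origin)
    structures = {
        "PTV": mk("PTV", ptv),
        "CTV": mk("CTV", ctv),
        "body": mk("body", body),
        "ipsilateral_lung": mk("ipsilateral_lung", lung_l),
        "whole_lung": mk("whole_lung", whole_lung),
        "heart": mk("heart", heart),
        "spinal_cord": mk("spinal_cord", cord),
    }
    dose = analytic_dose(structures["PTV"], params, rng)
    return PatientCase(id=case_id, image=image, structures=structures, dose=dose)


def analytic_dose(ptv: MaskVolume, params: PhantomParams,
                  rng: np.random.Generator | None = None) -> DoseVolume:
    """VMAT-morphology dose: Rx in the PTV, Gaussian falloff, lung corridor.

    dose(v) = Rx·(1+η(v)) inside the PTV (|η| ≤ noise_level, smooth),
    Rx·(1+η)·exp(−(s/σ)²) at signed distance s > 0 outside, plus a tangential
    low-dose corridor through the ipsilateral lung centred on the PTV's
    head–foot and anterior position; the spinal cord (posterior) sits far from
    the corridor, so its dose stays well below the lung dose.
    """
    if ptv.empty:
        raise ValueError("PTV is empty")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    rx = params.prescription
    sampling = ptv.spacing[::-1]
    inside = ptv.voxels > 0
    s = ndimage.distance_transform_edt(~inside, sampling=sampling)
    base = rx * np.exp(-((s / params.dose_sigma) ** 2))

    # corridor through the lung at the PTV's (y, z) position, all x (tangent-like)
    zz, yy, _ = _world_grids(replace(params, shape=ptv.shape,
                                     spacing=ptv.spacing))
    idx = np.argwhere(inside)
    cz = float(np.mean(zz[inside]))
    cy = float(np.mean(yy[inside]))
    bc = max(params.breast_semiaxes[2], 1.0)
    corridor = (params.corridor_amplitude * rx
                * np.exp(-((yy - cy) / 45.0) ** 2)
                * np.exp(-((zz - cz) / (1.2 * bc)) ** 2))
    # weak ambient scatter tail so distant organs (spinal cord) see a small,
    # nearly flat dose instead of exactly zero
    ambient = 0.03 * rx * np.exp(-s / 120.0)
    dose = np.maximum.reduce([base, corridor, ambient])
    eta = params.noise_level * _smooth_noise(ptv.shape, rng)
    dose = np.clip(dose * (1.0 + eta), 0.0, None)
    return DoseVolume(dose, ptv.spacing, ptv.origin, ptv.direction,
                      prescription=rx)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _sample_params(base: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """Per-case draw of anatomy parameters around the defaults."""
    breast_scale = rng.uniform(0.78, 1.26)
    return replace(
        base,
        body_semiaxes=tuple(s * rng.uniform(0.93, 1.07) for s in base.body_semiaxes),
        breast_semiaxes=tuple(s * breast_scale * rng.uniform(0.95, 1.05)
                              for s in base.breast_semiaxes),
        breast_angle_deg=base.breast_angle_deg + rng.uniform(-8.0, 8.0),
        breast_z_offset=rng.uniform(-15.0, 15.0),
        lung_semiaxes=tuple(s * rng.uniform(0.92, 1.08) for s in base.lung_semiaxes),
        heart_semiaxes=tuple(s * rng.uniform(0.92, 1.08) for s in base.heart_semiaxes),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def generate_cohort(n_atlas: int, n_test: int, seed: int = 0,
                    base: PhantomParams | None = None,
                    near_twin: bool = False,
                    out_dir: str | Path | None = None):
    """Draw an atlas cohort and a test cohort of phantom cases.

    Every case gets independent anatomy parameters sampled around the defaults
    (reproducible from ``seed``).  With ``near_twin=True`` the last atlas case
    is replaced by a mildly perturbed clone of the first test case — a known
    near-duplicate for retrieval tests.  If ``out_dir`` is given, per-case
    manifests are written beneath it.
    """
    if n_atlas < 1 or n_test < 1:
        raise ValueError("cohort sizes must be ≥ 1")
    base = base or PhantomParams()
    rng = np.random.default_rng(seed)
    atlas_params = [_sample_params(base, rng) for _ in range(n_atlas)]
    test_params = [_sample_params(base, rng) for _ in range(n_test)]
    if near_twin:
        twin = replace(
            test_params[0],
            breast_semiaxes=tuple(s * 1.02 for s in test_params[0].breast_semiaxes),
            breast_z_offset=test_params[0].breast_z_offset + 2.0,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        atlas_params[-1] = twin
    atlas = [generate_case(p, f"atlas{i:02d}") for i, p in enumerate(atlas_params)]
    test = [generate_case(p, f"test{i:02d}") for i, p in enumerate(test_params)]
    # test cases carry a reference plan dose for validation, but a real new
    # patient would arrive without one
    if out_dir is not None:
        out_dir = Path(out_dir)
        for case in atlas + test:
            write_case(case, out_dir / case.id)
    return atlas, test
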