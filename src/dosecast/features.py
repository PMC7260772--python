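"""Pairwise geometric similarity features between a new case and an atlas case.

Eleven features characterise patient geometry at different scales, all
constructed so that *smaller means more similar*:

1.  image MSD (global intensity similarity)
2.  1 / PTV Dice (target overlap, reciprocal-transformed)
3.  ipsilateral-lung OVH mean distance difference (mm)
4.  heart OVH mean distance difference (mm)
5.  PTV head–foot length difference (mm)
6.  1 / P_ovz (head–foot extent overlap, reciprocal-transformed)
7–11. |Δ| of the five 3D moment invariants J1, J2, J3, B3, B4 of the PTV shape

The overlap volume histogram (OVH) of an OAR relative to the PTV is the
cumulative distribution of the signed Euclidean distance from each OAR voxel to
the PTV (negative inside).  Two OVHs are compared through the mean absolute
difference of their inverse curves sampled at the 1–99% volume percentiles, so
the comparison carries mm units.

The moment invariants follow the classical second-order (J1, J2, J3) and
third/fourth-order (B3, B4) rotation-invariant combinations of central moments,
normalised by volume so they are additionally scale- and translation-invariant.
All features involving the atlas case are computed after rigid alignment of the
atlas onto the new patient's grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from .registration import RigidTransform, msd_metric
from .volumes import MaskVolume, PatientCase, resample_to_reference

__all__ = [
    "FEATURE_NAMES",
    "OVHCurve",
    "MomentInvariants",
    "FeatureVector",
    "ptv_dsc",
    "ovh_curve",
    "ovh_msd",
    "ptv_length_diff",
    "povz",
    "normalized_central_moments",
    "moment_invariants",
    "compute_feature_vector",
]

FEATURE_NAMES = (
    "image_msd",
    "ptv_dsc_recip",
    "ovh_msd_lung",
    "ovh_msd_heart",
    "ptv_length_diff",
    "povz_recip",
    "J1_diff",
    "J2_diff",
    "J3_diff",
    "B3_diff",
    "B4_diff",
)

#: cap for 1/DSC and 1/P_ovz when the raw value is 0 (no overlap at all)
RECIPROCAL_CAP = 1e3


# ---------------------------------------------------------------------------
# Dice and z-axis features
# ---------------------------------------------------------------------------

def ptv_dsc(mask1: MaskVolume, mask2: MaskVolume) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two masks on one grid."""
    if not mask1.same_grid(mask2):
        raise ValueError("masks must share a grid")
    a = mask1.voxels > 0
    b = mask2.voxels > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _z_interval(mask: MaskVolume) -> tuple[float, float]:
    """Head–foot interval [mm] covered by the mask (full voxel extents)."""
    if mask.empty:
        raise ValueError(f"mask '{mask.label}' is empty")
    ks = np.nonzero(mask.voxels.any(axis=(1, 2)))[0]
    sz = mask.spacing[2]
    z0 = mask.origin[2]  # assumes axis-aligned direction for the z extent
    lo = z0 + (ks.min() - 0.5) * sz
    hi = z0 + (ks.max() + 0.5) * sz
    return float(lo), float(hi)


def ptv_length_diff(mask1: MaskVolume, mask2: MaskVolume) -> float:
    """|z-extent(PTV1) − z-extent(PTV2)| in mm (head–foot direction)."""
    lo1, hi1 = _z_interval(mask1)
    lo2, hi2 = _z_interval(mask2)
    return float(abs((hi1 - lo1) - (hi2 - lo2)))


def povz(mask1: MaskVolume, mask2: MaskVolume) -> float:
    """Head–foot overlap metric 2·Z_overlap / (Z1 + Z2) ∈ [0, 1]."""
    lo1, hi1 = _z_interval(mask1)
    lo2, hi2 = _z_interval(mask2)
    overlap = max(0.0, min(hi1, hi2) - max(lo1, lo2))
    return float(2.0 * overlap / ((hi1 - lo1) + (hi2 - lo2)))


# ---------------------------------------------------------------------------
# Overlap volume histogram
# ---------------------------------------------------------------------------

@dataclass
class OVHCurve:
    """Cumulative OAR-volume fraction versus signed expansion distance (mm).

    ``distances`` holds the sorted per-voxel signed distances of the OAR to the
    PTV (negative where the OAR lies inside the PTV), ``fractions`` the matching
    cumulative volume fractions (k/N).  The inverse curve — distance at a given
    volume fraction — is what feature comparison uses.
    """

    distances: np.ndarray
    fractions: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if self.distances.size == 0:
            raise ValueError("empty OVH curve")
        if np.any(np.diff(self.fractions) < 0) or np.any(np.diff(self.distances) < 0):
            raise ValueError("OVH curve must be non-decreasing")
        if not np.isclose(self.fractions[-1], 1.0):
            raise ValueError("OVH curve must reach 1 at its maximum distance")

    def fraction_at(self, t: float) -> float:
        """Volume fraction of the OAR within signed distance ``t`` of the PTV."""
        return float(np.searchsorted(self.distances, t, side="right")
                     / self.distances.size)

    def distance_at_fraction(self, q: float) -> float:
        """Smallest distance at which the cumulative fraction reaches ``q``."""
        n = self.distances.size
        k = int(np.ceil(q * n)) - 1
        return float(self.distances[max(k, 0)])


def signed_distance_to_mask(mask: MaskVolume) -> np.ndarray:
    """Signed Euclidean distance map (mm) to the mask: negative inside."""
    inside = mask.voxels > 0
    sampling = mask.spacing[::-1]  # array axes (z, y, x)
    d_out = ndimage.distance_transform_edt(~inside, sampling=sampling)
    d_in = ndimage.distance_transform_edt(inside, sampling=sampling)
    return d_out - d_in


def ovh_curve(oar: MaskVolume, ptv: MaskVolume, n_bins: int | None = None) -> OVHCurve:
    """OVH of an OAR relative to the PTV via a signed distance transform.

    ``n_bins`` optionally thins the per-voxel distance sample to an evenly
    spaced subset (the exact inverse curve is kept by default).
    """
    if oar.empty:
        raise ValueError(f"OAR '{oar.label}' is empty")
    if ptv.empty:
        raise ValueError("PTV is empty")
    if not oar.same_grid(ptv):
        raise ValueError("OAR and PTV must share a grid")
    sd = signed_distance_to_mask(ptv)
    dists = np.sort(sd[oar.voxels > 0])
    if n_bins is not None and dists.size > n_bins:
        idx = np.unique(np.linspace(0, dists.size - 1, n_bins).round().astype(int))
        dists = dists[idx]
    fracs = np.arange(1, dists.size + 1) / dists.size
    return OVHCurve(distances=dists, fractions=fracs)


def ovh_msd(curve_a: OVHCurve, curve_b: OVHCurve,
            orientation: str = "distance") -> float:
    """Mean absolute OVH difference over the 1–99% volume percentiles.

    ``orientation="distance"`` (default) compares the inverse curves — the
    expansion distance (mm) at which each OAR reaches i% of its volume —
    yielding a mm-valued, patient-comparable quantity.
    ``orientation="volume"`` compares volume fractions at matched distances
    sampled from the pooled 1–99% distance percentiles instead.
    """
    qs = np.arange(1, 100) / 100.0
    if orientation == "distance":
        a = np.array([curve_a.distance_at_fraction(q) for q in qs])
        b = np.array([curve_b.distance_at_fraction(q) for q in qs])
    elif orientation == "volume":
        pooled = np.concatenate([curve_a.distances, curve_b.distances])
        ts = np.quantile(pooled, qs)
        a = np.array([curve_a.fraction_at(t) for t in ts])
        b = np.array([curve_b.fraction_at(t) for t in ts])
    else:
        raise ValueError("orientation must be 'distance' or 'volume'")
    return float(np.mean(np.abs(a - b)))


# ---------------------------------------------------------------------------
# 3D moment invariants
# ---------------------------------------------------------------------------

@dataclass
class MomentInvariants:
    """Second-order (J1, J2, J3) and third/fourth-order (B3, B4) invariants."""

    J1: float
    J2: float
    J3: float
    B3: float
    B4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.J1, self.J2, self.J3, self.B3, self.B4])


def _mask_world_coords(mask: MaskVolume) -> np.ndarray:
    """World (mm) coordinates of the centers of all 1-voxels, shape (N, 3)."""
    idx = np.argwhere(mask.voxels > 0)  # (z, y, x) indices
    ijk = idx[:, ::-1].astype(np.float64)  # → (x, y, z)
    D = np.asarray(mask.direction).reshape(3, 3)
    S = np.diag(mask.spacing)
    return ijk @ (D @ S).T + np.asarray(mask.origin)


def normalized_central_moments(mask: MaskVolume,
                               orders: Iterable[tuple[int, int, int]]
                               ) -> dict[tuple[int, int, int], float]:
    """Volume-normalised central moments η_pqr of a binary shape.

    Discrete midpoint approximation of μ_pqr = ∫(x−x̄)^p (y−ȳ)^q (z−z̄)^r f dV
    over voxel centers in world mm; η_pqr = μ_pqr / μ000^{(p+q+r)/3 + 1}.  The
    voxel volume enters every μ through the integral weight, so η is invariant
    to the rasterisation resolution up to discretisation error.
    """
    if mask.empty:
        raise ValueError("mask is empty")
    pts = _mask_world_coords(mask)
    centroid = pts.mean(axis=0)
    d = pts - centroid
    w = mask.voxel_volume_mm3
    mu000 = d.shape[0] * w
    out = {}
    for p, q, r in orders:
        mu = float(np.sum(d[:, 0] ** p * d[:, 1] ** q * d[:, 2] ** r)) * w
        out[(p, q, r)] = mu / mu000 ** ((p + q + r) / 3.0 + 1.0)
    return out


_ORDER2 = [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
_ORDER3 = [(3, 0, 0), (0, 3, 0), (0, 0, 3), (2, 1, 0), (2, 0, 1), (1, 2, 0),
           (1, 1, 1), (1, 0, 2), (0, 2, 1), (0, 1, 2)]
_ORDER4 = [(4, 0, 0), (0, 4, 0), (0, 0, 4), (3, 1, 0), (3, 0, 1), (2, 2, 0),
           (2, 1, 1), (2, 0, 2), (1, 3, 0), (1, 2, 1), (1, 1, 2), (1, 0, 3),
           (0, 3, 1), (0, 2, 2), (0, 1, 3)]


def moment_invariants(mask: MaskVolume) -> MomentInvariants:
    """The five rotation/translation/scale-invariant moment combinations."""
    eta = normalized_central_moments(mask, _ORDER2 + _ORDER3 + _ORDER4)

    def e(p, q, r):
        return eta[(p, q, r)]

    J1 = e(2, 0, 0) + e(0, 2, 0) + e(0, 0, 2)
    J2 = (e(2, 0, 0) * e(0, 2, 0) + e(2, 0, 0) * e(0, 0, 2)
          + e(0, 2, 0) * e(0, 0, 2)
          - e(1, 0, 1) ** 2 - e(1, 1, 0) ** 2 - e(0, 1, 1) ** 2)
    J3 = (e(2, 0, 0) * e(0, 2, 0) * e(0, 0, 2)
          - e(0, 0, 2) * e(1, 1, 0) ** 2
          - e(0, 2, 0) * e(1, 0, 1) ** 2
          - e(2, 0, 0) * e(0, 1, 1) ** 2
          + 2 * e(1, 1, 0) * e(1, 0, 1) * e(0, 1, 1))
    B3 = (e(3, 0, 0) ** 2 + e(0, 3, 0) ** 2 + e(0, 0, 3) ** 2
          + 3 * e(2, 1, 0) ** 2 + 3 * e(2, 0, 1) ** 2 + 3 * e(1, 2, 0) ** 2
          + 6 * e(1, 1, 1) ** 2 + 3 * e(1, 0, 2) ** 2
          + 3 * e(0, 2, 1) ** 2 + 3 * e(0, 1, 2) ** 2)
    B4 = (e(4, 0, 0) ** 2 + e(0, 4, 0) ** 2 + e(0, 0, 4) ** 2
          + 4 * e(3, 1, 0) ** 2 + 4 * e(3, 0, 1) ** 2 + 6 * e(2, 2, 0) ** 2
          + 12 * e(2, 1, 1) ** 2 + 6 * e(2, 0, 2) ** 2
          + 4 * e(1, 3, 0) ** 2 + 12 * e(1, 2, 1) ** 2 + 12 * e(1, 1, 2) ** 2
          + 4 * e(1, 0, 3) ** 2 + 4 * e(0, 3, 1) ** 2 + 6 * e(0, 2, 2) ** 2
          + 4 * e(0, 1, 3) ** 2)
    return MomentInvariants(J1=J1, J2=J2, J3=J3, B3=B3, B4=B4)


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The 11 named similarity features; every entry ≥ 0, smaller = more similar."""

    image_msd: float
    ptv_dsc_recip: float
    ovh_msd_lung: float
    ovh_msd_heart: float
    ptv_length_diff: float
    povz_recip: float
    J1_diff: float
    J2_diff: float
    J3_diff: float
    B3_diff: float
    B4_diff: float

    def __post_init__(self):
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"feature {name} is not finite")

    def to_series(self) -> pd.Series:
        return pd.Series({n: getattr(self, n) for n in FEATURE_NAMES})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def _guarded_reciprocal(x: float, cap: float) -> float:
    if x <= 1.0 / cap:
        return cap
    return 1.0 / x


def compute_feature_vector(new: PatientCase, atlas: PatientCase,
                           rigid: RigidTransform | None = None,
                           reciprocal_cap: float = RECIPROCAL_CAP,
                           ovh_orientation: str = "distance") -> FeatureVector:
    """All 11 features of an (atlas → new) pair after rigid alignment.

    The atlas image and masks are mapped through ``rigid`` and resampled onto
    the new patient's grid (image: trilinear; masks: nearest neighbour), then
    each feature is computed on the common grid.  Overlap features (PTV Dice
    and P_ovz) are stored as reciprocals, capped at ``reciprocal_cap`` when the
    raw value is zero, so every feature decreases with similarity and stays
    finite.
    """
    for label in ("PTV", "ipsilateral_lung", "heart"):
        for case in (new, atlas):
            if label not in case.structures:
                raise ValueError(f"case {case.id}: structure {label} required")
    rigid = rigid or RigidTransform.identity()
    tx = rigid.to_sitk()
    ref = new.image

    atlas_img = resample_to_reference(atlas.image, ref, "linear", transform=tx)
    a_ptv = resample_to_reference(atlas.structures["PTV"], ref, "nearest", transform=tx)
    a_lung = resample_to_reference(atlas.structures["ipsilateral_lung"], ref,
                                   "nearest", transform=tx)
    a_heart = resample_to_reference(atlas.structures["heart"], ref, "nearest",
                                    transform=tx)
    n_ptv = new.structures["PTV"]

    if a_ptv.empty:
        # alignment pushed the atlas PTV off the grid entirely: degenerate pair
        raise ValueError(f"atlas {atlas.id}: PTV empty after rigid alignment")

    dsc = ptv_dsc(n_ptv, a_ptv)
    pz = povz(n_ptv, a_ptv)

    inv_new = moment_invariants(n_ptv)
    # invariants are alignment-independent; use the native-space atlas PTV to
    # avoid resampling error in the shape descriptors
    inv_atl = moment_invariants(atlas.structures["PTV"])

    curves_new = {
        "lung": ovh_curve(new.structures["ipsilateral_lung"], n_ptv),
        "heart": ovh_curve(new.structures["heart"], n_ptv),
    }
    curves_atl = {
        "lung": ovh_curve(a_lung, a_ptv) if not a_lung.empty
        else ovh_curve(atlas.structures["ipsilateral_lung"], atlas.structures["PTV"]),
        "heart": ovh_curve(a_heart, a_ptv) if not a_heart.empty
        else ovh_curve(atlas.structures["heart"], atlas.structures["PTV"]),
    }

    return FeatureVector(
        image_msd=msd_metric(new.image, atlas_img),
        ptv_dsc_recip=_guarded_reciprocal(dsc, reciprocal_cap),
        ovh_msd_lung=ovh_msd(curves_new["lung"], curves_atl["lung"],
                             orientation=ovh_orientation),
        ovh_msd_heart=ovh_msd(curves_new["heart"], curves_atl["heart"],
                              orientation=ovh_orientation),
        ptv_length_diff=ptv_length_diff(n_ptv, a_ptv),
        povz_recip=_guarded_reciprocal(pz, reciprocal_cap),
        J1_diff=abs(inv_new.J1 - inv_atl.J1),
        J2_diff=abs(inv_new.J2 - inv_atl.J2),
        J3_diff=abs(inv_new.J3 - inv_atl.J3),
        B3_diff=abs(inv_new.B3 - inv_atl.B3),
        B4_diff=abs(inv_new.B4 - inv_atl.B4),
    )
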