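"""Volume data model and I/O.

Conventions
-----------
Voxel arrays are indexed ``(z, y, x)`` (the order :func:`SimpleITK.GetArrayFromImage`
returns), while ``spacing``/``origin``/``direction`` follow the SimpleITK/ITK world
convention: ``(x, y, z)`` in mm, LPS orientation, 0-based indices.  All pairwise
computations in the rest of the package happen after resampling one case onto the
other's grid, so every metric is defined on a single common grid.

Masks are stored one structure per volume (not a multi-label map) so that nested
structures (whole lung containing the ipsilateral lung) stay representable.  Dose is
carried in cGy together with the prescription dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "MaskVolume",
    "DoseVolume",
    "PatientCase",
    "GridMismatchError",
    "read_case",
    "write_case",
    "resample_to_reference",
    "roi_volume_cc",
]

#: structures every case must carry (CTV is optional)
REQUIRED_STRUCTURES = ("PTV", "ipsilateral_lung", "whole_lung", "heart", "spinal_cord")

GRID_TOL_MM = 1e-4


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def _as_tuple(x, n=3):
    t = tuple(float(v) for v in np.ravel(x))
    if len(t) != n:
        raise ValueError(f"expected {n} components, got {len(t)}")
    return t


@dataclass
class ImageVolume:
    """A 3D scalar volume with world-grid metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar intensities (arbitrary units, e.g. CT numbers).
    spacing : (sx, sy, sz) voxel size in mm, strictly positive.
    origin : world coordinate (mm) of voxel index (0, 0, 0).
    direction : row-major 3x3 direction cosine matrix (9-tuple), orthonormal.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    direction: tuple = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = _as_tuple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive on all axes")
        self.origin = _as_tuple(self.origin)
        self.direction = _as_tuple(self.direction, 9)
        D = np.asarray(self.direction).reshape(3, 3)
        if not np.allclose(D @ D.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    # -- grid helpers -----------------------------------------------------
    @property
    def shape(self):
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def grid_tuple(self):
        return (self.shape, self.spacing, self.origin, self.direction)

    def same_grid(self, other, tol: float = GRID_TOL_MM) -> bool:
        if self.shape != other.shape:
            return False
        return (
            np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=1e-6)
        )

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self, dtype=None) -> sitk.Image:
        arr = self.voxels if dtype is None else self.voxels.astype(dtype)
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        return cls(
            voxels=sitk.GetArrayFromImage(img),
            spacing=img.GetSpacing(),
            origin=img.GetOrigin(),
            direction=img.GetDirection(),
        )

    def with_voxels(self, voxels: np.ndarray):
        return replace(self, voxels=voxels)


@dataclass
class MaskVolume(ImageVolume):
    """Binary structure mask aligned to a reference image grid."""

    label: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask '{self.label}' must be binary (0/1)")
        self.voxels = self.voxels.astype(np.uint8)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def empty(self) -> bool:
        return self.n_voxels == 0


@dataclass
class DoseVolume(ImageVolume):
    """Dose grid in cGy with its prescription dose."""

    prescription: float = 5000.0

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(np.float64)
        if np.any(self.voxels < 0):
            raise ValueError("dose values must be non-negative")
        if not self.prescription > 0:
            raise ValueError("prescription dose must be positive")


@dataclass
class PatientCase:
    """One patient: image, structure masks and (for atlas cases) planned dose."""

    id: str
    image: ImageVolume
    structures: Mapping[str, MaskVolume] = field(default_factory=dict)
    dose: DoseVolume | None = None

    def __post_init__(self):
        if "PTV" not in self.structures:
            raise ValueError("structure PTV required")
        if self.structures["PTV"].empty:
            raise ValueError("structure PTV must be non-empty")
        for label, mask in self.structures.items():
            if not mask.same_grid(self.image):
                raise GridMismatchError(
                    f"case {self.id}: structure '{label}' grid differs from image grid"
                )
        if self.dose is not None and not self.dose.same_grid(self.image):
            raise GridMismatchError(f"case {self.id}: dose grid differs from image grid")

    @property
    def ptv(self) -> MaskVolume:
        return self.structures["PTV"]

    @property
    def has_dose(self) -> bool:
        return self.dose is not None


# ---------------------------------------------------------------------------
# I/O: JSON manifest + NIfTI / MetaImage component volumes
# ---------------------------------------------------------------------------

def read_case(manifest: str | Path) -> PatientCase:
    """Read a :class:`PatientCase` from a JSON manifest.

    The manifest lists relative paths for the image, each structure mask and
    (optionally) the dose, plus the case id and prescription in cGy::

        {"id": "case01", "image": "image.nii.gz",
         "structures": {"PTV": "ptv.nii.gz", ...},
         "dose": "dose.nii.gz", "prescription_cgy": 5000}

    All component grids must agree to within 0.1 µm; a mismatching component is
    a hard error naming the offender.
    """
    manifest = Path(manifest)
    meta = json.loads(manifest.read_text())
    root = manifest.parent
    image = ImageVolume.from_sitk(sitk.ReadImage(str(root / meta["image"])))
    structures = {}
    for label, rel in meta.get("structures", {}).items():
        vol = ImageVolume.from_sitk(sitk.ReadImage(str(root / rel)))
        arr = np.rint(vol.voxels).astype(np.uint8)
        mask = MaskVolume(arr, vol.spacing, vol.origin, vol.direction, label=label)
        if not mask.same_grid(image):
            raise GridMismatchError(f"structure '{label}' grid differs from image grid")
        structures[label] = mask
    if "PTV" not in structures:
        raise ValueError("structure PTV required")
    dose = None
    if meta.get("dose"):
        vol = ImageVolume.from_sitk(sitk.ReadImage(str(root / meta["dose"])))
        if not vol.same_grid(image):
            raise GridMismatchError("dose grid differs from image grid")
        dose = DoseVolume(
            vol.voxels, vol.spacing, vol.origin, vol.direction,
            prescription=float(meta.get("prescription_cgy", 5000.0)),
        )
    return PatientCase(id=meta.get("id", manifest.stem), image=image,
                       structures=structures, dose=dose)


def write_case(case: PatientCase, out_dir: str | Path, fmt: str = "nii.gz") -> Path:
    """Write a case to ``out_dir`` and return the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"id": case.id, "image": f"image.{fmt}", "structures": {}}
    sitk.WriteImage(case.image.to_sitk(), str(out_dir / meta["image"]))
    for label, mask in case.structures.items():
        rel = f"{label}.{fmt}"
        sitk.WriteImage(mask.to_sitk(), str(out_dir / rel))
        meta["structures"][label] = rel
    if case.dose is not None:
        meta["dose"] = f"dose.{fmt}"
        meta["prescription_cgy"] = case.dose.prescription
        sitk.WriteImage(case.dose.to_sitk(), str(out_dir / meta["dose"]))
    manifest = out_dir / "case.json"
    manifest.write_text(json.dumps(meta, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Resampling & simple geometry
# ---------------------------------------------------------------------------

def resample_to_reference(moving, reference: ImageVolume, interp: str = "linear",
                          transform: sitk.Transform | None = None,
                          default_value: float = 0.0):
    """Resample ``moving`` onto the grid of ``reference``.

    Masks must use ``interp="nearest"`` so the output stays binary; dose and
    images use trilinear interpolation.  Returns the same kind of volume as
    ``moving`` (mask label / dose prescription are preserved).
    """
    if 0 in reference.shape:
        raise ValueError("reference grid has zero extent")
    interpolator = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[interp]
    img = moving.to_sitk(dtype=np.float64)
    ref = reference.to_sitk()
    if transform is None:
        transform = sitk.Transform()
    out = sitk.Resample(img, ref, transform, interpolator, default_value)
    arr = sitk.GetArrayFromImage(out)
    if isinstance(moving, MaskVolume):
        return MaskVolume(np.rint(arr).astype(np.uint8), reference.spacing,
                          reference.origin, reference.direction, label=moving.label)
    if isinstance(moving, DoseVolume):
        return DoseVolume(np.maximum(arr, 0.0), reference.spacing, reference.origin,
                          reference.direction, prescription=moving.prescription)
    return ImageVolume(arr, reference.spacing, reference.origin, reference.direction)


def roi_volume_cc(mask: MaskVolume) -> float:
    """Structure volume in cm³: 1-voxel count times voxel volume (mm³ → cm³)."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0
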