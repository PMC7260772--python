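"""Dose-prediction quality metrics and statistical method comparison.

Per case, nine metrics mirror standard plan-comparison practice:

- mean absolute dose difference (MAD, cGy) over five ROIs
  (PTV, ipsilateral lung, heart, whole lung, spinal cord);
- Dice of the 80% and 100% prescription isodose regions;
- 3D gamma pass rates at 3 mm / 3% and 5 mm / 5% (global normalisation to the
  prescription dose, evaluated inside the ≥80%-of-prescription reference region).

Across cases, methods are compared with a Friedman test per metric, followed by
pairwise Wilcoxon signed-rank post-hoc tests (exact p-values at small n) when
the Friedman test rejects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import DoseVolume, MaskVolume

__all__ = [
    "GammaCriteria",
    "EvaluationReport",
    "MAD_ROIS",
    "METRIC_NAMES",
    "mad_roi",
    "dose_dsc",
    "gamma_pass_rate",
    "evaluate_case",
    "compare_methods",
]

MAD_ROIS = ("PTV", "ipsilateral_lung", "heart", "whole_lung", "spinal_cord")

METRIC_NAMES = (
    "mad_PTV", "mad_ipsilateral_lung", "mad_heart", "mad_whole_lung",
    "mad_spinal_cord", "dsc_080", "dsc_100", "gamma_33", "gamma_55",
)


@dataclass
class GammaCriteria:
    """Distance-to-agreement (mm) and dose-difference (% of Rx) tolerances."""

    dta_mm: float = 3.0
    dose_pct: float = 3.0
    region_fraction: float = 0.8  # evaluate where ref ≥ this fraction of Rx

    def __post_init__(self):
        if self.dta_mm <= 0 or self.dose_pct <= 0:
            raise ValueError("gamma tolerances must be positive")


@dataclass
class EvaluationReport:
    """Nine per-case metrics for one prediction method."""

    case_id: str
    method: str
    mad: Mapping[str, float]
    dsc_080: float
    dsc_100: float
    gamma_33: float
    gamma_55: float

    def to_series(self) -> pd.Series:
        d = {f"mad_{roi}": self.mad[roi] for roi in self.mad}
        d.update(dsc_080=self.dsc_080, dsc_100=self.dsc_100,
                 gamma_33=self.gamma_33, gamma_55=self.gamma_55)
        return pd.Series(d, name=(self.case_id, self.method))


# ---------------------------------------------------------------------------
# Voxelwise metrics
# ---------------------------------------------------------------------------

def mad_roi(pred: DoseVolume, ref: DoseVolume, roi: MaskVolume) -> float:
    """Mean absolute dose difference (cGy) over the ROI voxels."""
    if not (pred.same_grid(ref) and pred.same_grid(roi)):
        raise ValueError("pred, ref and roi must share a grid")
    sel = roi.voxels > 0
    if not sel.any():
        raise ValueError(f"ROI '{roi.label}' is empty")
    return float(np.mean(np.abs(pred.voxels[sel] - ref.voxels[sel])))


def dose_dsc(pred: DoseVolume, ref: DoseVolume, level: float) -> float:
    """Dice overlap of the {dose ≥ level} regions of two dose grids."""
    if not pred.same_grid(ref):
        raise ValueError("pred and ref must share a grid")
    a = pred.voxels >= level
    b = ref.voxels >= level
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError(f"no voxel reaches {level} cGy in either distribution")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _oversampled_pred(pred: np.ndarray, k: int) -> np.ndarray:
    """Trilinear refinement of ``pred`` onto a k× grid of voxel-center samples.

    Output node ``m`` lies at voxel coordinate ``m / k``; nodes beyond the last
    voxel center are not generated, so every sample is exact interpolation.
    """
    if k == 1:
        return pred.astype(np.float64)
    coords = [np.arange((n - 1) * k + 1) / k for n in pred.shape]
    grid = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(pred.astype(np.float64), np.stack(grid),
                                   order=1, mode="nearest")


def gamma_pass_rate(pred: DoseVolume, ref: DoseVolume,
                    criteria: GammaCriteria | None = None,
                    rx: float | None = None,
                    oversample: int = 3,
                    window_factor: float = 2.0) -> float:
    """Fraction of reference voxels with 3D gamma ≤ 1.

    For each reference voxel ``r_m`` inside the evaluation region
    (ref ≥ ``region_fraction``·Rx), gamma is the minimum over candidate points
    ``r_p`` of ``sqrt(|r_p−r_m|²/Δr_M² + (d_p−d_m)²/Δd_M²)`` with the dose
    tolerance Δd_M taken globally as a percentage of the prescription.
    Candidates are the nodes of the predicted dose trilinearly refined
    ``oversample``× per axis, searched within ``window_factor``·Δr_M of each
    voxel.  Any candidate farther than Δr_M fails on the spatial term alone, so
    the pass rate is exact for any window_factor ≥ 1.
    """
    criteria = criteria or GammaCriteria()
    if not pred.same_grid(ref):
        raise ValueError("pred and ref must share a grid")
    rx = float(rx if rx is not None else ref.prescription)
    if rx <= 0:
        raise ValueError("prescription must be positive")

    region = ref.voxels >= criteria.region_fraction * rx
    if not region.any():
        raise ValueError("gamma evaluation region is empty")

    dd = criteria.dose_pct / 100.0 * rx
    dta = criteria.dta_mm
    k = int(oversample)
    spacing_zyx = np.asarray(ref.spacing[::-1], dtype=np.float64)
    step = spacing_zyx / k  # refined grid step per array axis, mm

    fine = _oversampled_pred(pred.voxels, k)
    n_fine = np.array(fine.shape)

    idx = np.argwhere(region)  # (N, 3) in (z, y, x)
    base = idx * k
    d_m = ref.voxels[region].astype(np.float64)

    max_steps = np.floor(window_factor * dta / step).astype(int)
    best = np.full(d_m.shape, np.inf)
    offsets = [range(-m, m + 1) for m in max_steps]
    for oz, oy, ox in itertools.product(*offsets):
        off = np.array([oz, oy, ox])
        r2 = float(np.sum((off * step) ** 2))
        if r2 > (window_factor * dta) ** 2:
            continue
        pos = base + off
        valid = np.all((pos >= 0) & (pos < n_fine), axis=1)
        if not valid.any():
            continue
        pv = pos[valid]
        d_p = fine[pv[:, 0], pv[:, 1], pv[:, 2]]
        g2 = r2 / dta ** 2 + (d_p - d_m[valid]) ** 2 / dd ** 2
        np.minimum.at(best, np.nonzero(valid)[0], g2)
    return float(np.mean(best <= 1.0))


def evaluate_case(pred: DoseVolume, ref_case, method: str = "",
                  oversample: int = 3) -> EvaluationReport:
    """All nine metrics of a predicted dose against a case's planned dose."""
    ref = ref_case.dose
    if ref is None:
        raise ValueError(f"case {ref_case.id} has no reference dose")
    rx = ref.prescription
    mad = {roi: mad_roi(pred, ref, ref_case.structures[roi])
           for roi in MAD_ROIS if roi in ref_case.structures}
    return EvaluationReport(
        case_id=ref_case.id,
        method=method,
        mad=mad,
        dsc_080=dose_dsc(pred, ref, 0.8 * rx),
        dsc_100=dose_dsc(pred, ref, 1.0 * rx),
        gamma_33=gamma_pass_rate(pred, ref, GammaCriteria(3.0, 3.0), rx=rx,
                                 oversample=oversample),
        gamma_55=gamma_pass_rate(pred, ref, GammaCriteria(5.0, 5.0), rx=rx,
                                 oversample=oversample),
    )


# ---------------------------------------------------------------------------
# Method comparison statistics
# ---------------------------------------------------------------------------

def reports_to_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Long-format DataFrame: one row per (case, method) with metric columns."""
    rows = []
    for r in reports:
        s = r.to_series()
        s["case_id"] = r.case_id
        s["method"] = r.method
        rows.append(s)
    return pd.DataFrame(rows).reset_index(drop=True)


def compare_methods(reports: Sequence[EvaluationReport] | pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Friedman test per metric across ≥3 methods, Wilcoxon post hoc if rejected.

    Returns a table with one row per metric: the Friedman p-value and, where it
    falls below ``alpha``, the p-value of every pairwise exact Wilcoxon
    signed-rank contrast (columns ``wilcoxon_<m1>__<m2>``).
    """
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    methods = sorted(df["method"].unique())
    if len(methods) < 3:
        raise ValueError("compare_methods needs at least three methods")
    case_sets = {m: set(df.loc[df.method == m, "case_id"]) for m in methods}
    ref_set = case_sets[methods[0]]
    if any(cs != ref_set for cs in case_sets.values()):
        raise ValueError("methods were evaluated on different case sets")

    metric_cols = [c for c in df.columns if c not in ("case_id", "method")]
    wide = {m: df[df.method == m].set_index("case_id").loc[sorted(ref_set)]
            for m in methods}
    out = []
    for metric in metric_cols:
        cols = [wide[m][metric].to_numpy(dtype=float) for m in methods]
        if all(np.array_equal(cols[0], c) for c in cols[1:]):
            # identical methods: no evidence of any difference
            stat_p = 1.0
            stat = 0.0
        else:
            stat, stat_p = stats.friedmanchisquare(*cols)
        row = {"metric": metric, "friedman_chi2": stat, "friedman_p": stat_p}
        if stat_p < alpha:
            for m1, m2 in itertools.combinations(methods, 2):
                a, b = wide[m1][metric], wide[m2][metric]
                if np.array_equal(a.to_numpy(), b.to_numpy()):
                    p = 1.0
                else:
                    mode = "exact" if len(a) <= 25 else "approx"
                    p = stats.wilcoxon(a, b, method=mode).pvalue
                row[f"wilcoxon_{m1}__{m2}"] = p
        out.append(row)
    return pd.DataFrame(out).set_index("metric")
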