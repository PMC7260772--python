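"""Atlas selection and dose fusion: SIM, WEI_A and WEI_F strategies.

SIM rigidly registers every atlas case to the new patient, scores each pair with
the comprehensive score F, picks the most similar atlas (minimum F by default)
and runs the full deformable chain for that atlas only.  WEI deformably
registers *all* atlases, warps every dose onto the new grid and blends them
voxelwise, d_i = Σ_j ω_j d_j — with uniform weights ω_j = 1/n (WEI_A) or
similarity-derived weights (WEI_F) obtained by min-max rescaling the scores,

    F'_j = (F_max − F_j) / (F_max − F_min),      ω_j = F'_j / Σ_k F'_k,

so the most similar atlas receives the largest weight and the least similar
weight zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .features import compute_feature_vector
from .registration import (RegistrationConfig, build_chain, register_rigid,
                           warp_dose)
from .scoring import ComprehensiveScoreModel
from .volumes import DoseVolume, PatientCase

__all__ = [
    "AtlasWeights",
    "PredictionResult",
    "weights_from_scores",
    "AtlasDosePredictor",
    "predict_sim",
    "predict_wei",
]


@dataclass
class AtlasWeights:
    """Convex per-atlas fusion weights (ω_j ≥ 0, Σω_j = 1)."""

    weights: np.ndarray
    atlas_ids: tuple

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        if len(self.atlas_ids) != self.weights.size:
            raise ValueError("one weight per atlas required")


@dataclass
class PredictionResult:
    """Predicted dose on the new grid plus the provenance of the prediction."""

    dose: DoseVolume
    method: str
    selected_id: str | None = None
    weights: AtlasWeights | None = None
    scores: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.method == "SIM" and self.selected_id is None:
            raise ValueError("SIM result requires the selected atlas id")
        if self.method in ("WEI_A", "WEI_F") and self.weights is None:
            raise ValueError("WEI result requires the atlas weights")


def weights_from_scores(f_scores: Sequence[float],
                        atlas_ids: Sequence[str] | None = None) -> AtlasWeights:
    """Min-max rescaled similarity weights from comprehensive scores.

    The most similar atlas (minimum F) gets the largest weight; the least
    similar gets zero.  All-equal scores degrade to uniform weights with a
    warning (the rescaling is then 0/0).
    """
    f = np.asarray(f_scores, dtype=np.float64)
    if f.size < 2:
        raise ValueError("need at least two atlas scores")
    if not np.all(np.isfinite(f)):
        raise ValueError("scores must be finite")
    ids = tuple(atlas_ids) if atlas_ids is not None else tuple(range(f.size))
    span = f.max() - f.min()
    if span == 0:
        warnings.warn("all comprehensive scores equal; using uniform weights")
        w = np.full(f.size, 1.0 / f.size)
    else:
        fp = (f.max() - f) / span
        w = fp / fp.sum()
    return AtlasWeights(weights=w, atlas_ids=ids)


class AtlasDosePredictor(BaseEstimator):
    """Atlas-based dose predictor with pluggable fusion strategy.

    Parameters
    ----------
    method : {"sim", "wei_a", "wei_f"}
        Single most-similar atlas, uniform-weight fusion, or score-weighted
        fusion.
    score_model : fitted :class:`ComprehensiveScoreModel` or None
        Required for "sim" and "wei_f" (not for "wei_a").
    select : {"min", "max"}
        Score polarity for similarity: features shrink with similarity, so the
        most similar atlas carries the *minimum* F (default).  "max" flips the
        convention.
    registration : :class:`RegistrationConfig` or None.

    After ``fit(atlas_cases)`` the atlas database is held in ``atlas_cases_``;
    ``predict(new_case)`` returns a :class:`PredictionResult`.
    """

    def __init__(self, method: str = "wei_f",
                 score_model: ComprehensiveScoreModel | None = None,
                 select: str = "min",
                 registration: RegistrationConfig | None = None):
        self.method = method
        self.score_model = score_model
        self.select = select
        self.registration = registration

    # -- sklearn plumbing -------------------------------------------------
    def fit(self, atlas_cases: Sequence[PatientCase], y=None):
        cases = list(atlas_cases)
        if not cases:
            raise ValueError("atlas database is empty")
        for c in cases:
            if not c.has_dose:
                raise ValueError(f"atlas case {c.id} has no dose")
        if self.method not in ("sim", "wei_a", "wei_f"):
            raise ValueError(f"unknown method '{self.method}'")
        if self.select not in ("min", "max"):
            raise ValueError("select must be 'min' or 'max'")
        if self.method in ("sim", "wei_f") and len(cases) > 1 \
                and self.score_model is None:
            raise ValueError(f"method '{self.method}' needs a fitted score_model")
        self.atlas_cases_ = cases
        self.atlas_ids_ = tuple(c.id for c in cases)
        return self

    # -- scoring ----------------------------------------------------------
    def rigid_align(self, new: PatientCase) -> dict[str, "object"]:
        """Rigid transform of every atlas onto the new patient (cached per call)."""
        config = self.registration or RegistrationConfig()
        return {a.id: register_rigid(new.image, a.image, config)
                for a in self.atlas_cases_}

    def score_atlases(self, new: PatientCase, rigids=None) -> dict[str, float]:
        """Comprehensive score of every (atlas → new) pair after rigid alignment."""
        rigids = rigids or self.rigid_align(new)
        scores = {}
        for atlas in self.atlas_cases_:
            fv = compute_feature_vector(new, atlas, rigids[atlas.id])
            scores[atlas.id] = float(self.score_model.score_samples(fv)[0])
        return scores

    def warp_atlas_doses(self, new: PatientCase, rigids=None) -> dict[str, DoseVolume]:
        """Full-chain warp of every atlas dose onto the new grid (cacheable)."""
        config = self.registration or RegistrationConfig()
        rigids = rigids or {}
        out = {}
        for atlas in self.atlas_cases_:
            chain = build_chain(new, atlas, config, rigid=rigids.get(atlas.id))
            out[atlas.id] = warp_dose(atlas.dose, chain, new.image)
        return out

    # -- prediction -------------------------------------------------------
    def predict(self, new: PatientCase,
                warped: Mapping[str, DoseVolume] | None = None) -> PredictionResult:
        """Predict the new patient's 3D dose with the configured strategy.

        ``warped`` optionally injects precomputed full-chain warped doses keyed
        by atlas id (lets WEI_A and WEI_F share one registration pass).
        """
        if not hasattr(self, "atlas_cases_"):
            raise ValueError("predictor is not fitted")
        if self.method == "sim":
            return self._predict_sim(new, warped)
        return self._predict_wei(new, warped)

    def _predict_sim(self, new, warped):
        rigids = None
        if len(self.atlas_cases_) == 1:
            selected = self.atlas_cases_[0]
            scores = {selected.id: 0.0}
        else:
            rigids = self.rigid_align(new)
            scores = self.score_atlases(new, rigids)
            pick = min if self.select == "min" else max
            sel_id = pick(scores, key=scores.get)
            selected = next(c for c in self.atlas_cases_ if c.id == sel_id)
        if warped is not None and selected.id in warped:
            dose = warped[selected.id]
        else:
            config = self.registration or RegistrationConfig()
            rigid = rigids.get(selected.id) if rigids else None
            chain = build_chain(new, selected, config, rigid=rigid)
            dose = warp_dose(selected.dose, chain, new.image)
        return PredictionResult(dose=dose, method="SIM", selected_id=selected.id,
                                scores=scores)

    def _predict_wei(self, new, warped):
        n = len(self.atlas_cases_)
        scores = None
        rigids = None
        if self.method == "wei_f" and n > 1:
            rigids = self.rigid_align(new)
            scores = self.score_atlases(new, rigids)
            f = np.array([scores[i] for i in self.atlas_ids_])
            if self.select == "max":
                f = -f
            w = weights_from_scores(f, self.atlas_ids_)
        else:
            w = AtlasWeights(np.full(n, 1.0 / n), self.atlas_ids_)
        if warped is None:
            warped = self.warp_atlas_doses(new, rigids)
        acc = None
        for wt, aid in zip(w.weights, w.atlas_ids):
            d = warped[aid].voxels
            acc = wt * d if acc is None else acc + wt * d
        rx = self.atlas_cases_[0].dose.prescription
        dose = DoseVolume(acc, new.image.spacing, new.image.origin,
                          new.image.direction, prescription=rx)
        tag = "WEI_A" if self.method == "wei_a" else "WEI_F"
        return PredictionResult(dose=dose, method=tag, weights=w, scores=scores)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def predict_sim(new: PatientCase, atlas_db: Sequence[PatientCase],
                model: ComprehensiveScoreModel | None = None,
                **kwargs) -> PredictionResult:
    """Most-similar-atlas prediction (thin wrapper over the estimator)."""
    return AtlasDosePredictor(method="sim", score_model=model,
                              **kwargs).fit(atlas_db).predict(new)


def predict_wei(new: PatientCase, atlas_db: Sequence[PatientCase],
                weights: AtlasWeights | str = "uniform",
                model: ComprehensiveScoreModel | None = None,
                warped: Mapping[str, DoseVolume] | None = None,
                **kwargs) -> PredictionResult:
    """Weighted multi-atlas fusion.

    ``weights`` may be "uniform" (WEI_A), "score" (WEI_F, needs ``model``) or an
    explicit :class:`AtlasWeights` (e.g. one-hot for testing the SIM
    equivalence).
    """
    if isinstance(weights, AtlasWeights):
        pred = AtlasDosePredictor(method="wei_a", **kwargs).fit(atlas_db)
        if len(weights.atlas_ids) != len(pred.atlas_cases_):
            raise ValueError("weight/atlas count mismatch")
        if warped is None:
            warped = pred.warp_atlas_doses(new)
        acc = None
        for wt, aid in zip(weights.weights, weights.atlas_ids):
            d = warped[aid].voxels
            acc = wt * d if acc is None else acc + wt * d
        rx = pred.atlas_cases_[0].dose.prescription
        dose = DoseVolume(acc, new.image.spacing, new.image.origin,
                          new.image.direction, prescription=rx)
        return PredictionResult(dose=dose, method="WEI_F", weights=weights)
    method = {"uniform": "wei_a", "score": "wei_f"}[weights]
    est = AtlasDosePredictor(method=method, score_model=model, **kwargs)
    return est.fit(atlas_db).predict(new, warped=warped)
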