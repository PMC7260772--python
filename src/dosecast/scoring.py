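"""Feature screening and the factor-analysis comprehensive similarity score.

Workflow: the ordered-pair atlas experiment produces a table of the 11 geometric
features together with 9 dose-prediction error outcomes for every ordered atlas
pair (n·(n−1) rows for an n-case atlas).  Features are screened by Spearman rank
correlation against the outcomes, the retained set is checked for factorability
(KMO > 0.5, Bartlett sphericity p < 0.05), and a principal-component factor
analysis with varimax rotation and Kaiser retention (eigenvalue > 1) compresses
them into a handful of factors.  A pair's comprehensive score is the
eigenvalue-weighted mean of its factor scores,

    F = Σ_i λ_i F_i / Σ_i λ_i,

where λ_i are the rotated factors' explained variances (sums of squared rotated
loadings) and F_i the regression-method (Thomson) factor scores.  Features are
built so smaller means more similar, hence a lower F marks a more similar atlas.

`ComprehensiveScoreModel` is a scikit-learn style transformer: `fit` on the
feature table, `transform` to factor scores, `score_samples` to F.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .features import FEATURE_NAMES, FeatureVector, compute_feature_vector
from .registration import (RegistrationConfig, build_chain, register_rigid,
                           warp_dose)
from .evaluation import METRIC_NAMES, evaluate_case

__all__ = [
    "spearman_screen",
    "kmo_bartlett",
    "varimax",
    "ComprehensiveScoreModel",
    "fit_factor_model",
    "comprehensive_score",
    "pairwise_atlas_experiment",
]

OUTCOME_NAMES = METRIC_NAMES  # 5 ROI MADs + 2 isodose DSCs + 2 gamma rates


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def spearman_screen(table: pd.DataFrame, alpha: float = 0.05,
                    features: Sequence[str] = FEATURE_NAMES,
                    outcomes: Sequence[str] = OUTCOME_NAMES):
    """Retain features significantly rank-correlated with ≥1 outcome.

    Returns ``(retained, rho, p)`` where ``rho`` and ``p`` are feature × outcome
    DataFrames.  A constant feature has no defined rank correlation and is
    dropped with a warning.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 pair rows to screen features")
    rho = pd.DataFrame(index=list(features), columns=list(outcomes), dtype=float)
    pvals = rho.copy()
    retained = []
    for f in features:
        x = table[f].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature '{f}' is constant; Spearman rho undefined, dropped")
            continue
        for o in outcomes:
            r, p = stats.spearmanr(x, table[o].to_numpy(dtype=float))
            rho.loc[f, o] = r
            pvals.loc[f, o] = p
        if (pvals.loc[f] < alpha).any():
            retained.append(f)
    return retained, rho, pvals


def kmo_bartlett(X: np.ndarray | pd.DataFrame) -> dict:
    """Kaiser–Meyer–Olkin sampling adequacy and Bartlett's sphericity test.

    KMO compares observed correlations against anti-image partial correlations;
    Bartlett tests H0: the correlation matrix is the identity, with
    χ² = −(n−1−(2p+5)/6)·ln det R on p(p−1)/2 degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than feature columns")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant feature column; remove it before testing")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular correlation matrix; remove redundant features")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular correlation matrix; remove redundant features") from err
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(p, dtype=bool)
    kmo = float(np.sum(R[off] ** 2) / (np.sum(R[off] ** 2) + np.sum(partial[off] ** 2)))
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    dof = p * (p - 1) / 2.0
    bart_p = float(stats.chi2.sf(chi2, dof))
    return {"kmo": kmo, "bartlett_chi2": float(chi2), "bartlett_p": bart_p}


# ---------------------------------------------------------------------------
# Factor analysis (principal-component extraction + varimax)
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-10
            ) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix (features × factors)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag(np.sum(Lr ** 2, axis=0)) / p))
        R = u @ vt
        var_new = float(np.sum(s))
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return L @ R


class ComprehensiveScoreModel(BaseEstimator, TransformerMixin):
    """Factor-analysis similarity score over the geometric feature table.

    Parameters
    ----------
    n_factors : int or None
        Number of factors; None applies the Kaiser criterion (correlation-matrix
        eigenvalue > 1).
    rotation : {"varimax", None}
        Orthogonal rotation of the principal-component loadings.
    kmo_threshold, bartlett_alpha : factorability gates checked during ``fit``
        (set ``enforce_gates=False`` to record them without failing).

    Attributes
    ----------
    feature_names_in_ : retained feature names (fit input columns).
    mean_, scale_ : standardisation parameters of the fitting table.
    eigenvalues_all_ : all correlation-matrix eigenvalues, descending.
    n_factors_ : retained factor count.
    loadings_ : rotated loading matrix, features × factors.
    eigenvalues_ : rotated explained variances (sums of squared loadings).
    explained_variance_ratio_ : fraction of total feature variance retained.
    kmo_, bartlett_p_ : factorability diagnostics of the fitting table.
    """

    def __init__(self, n_factors: int | None = None, rotation: str | None = "varimax",
                 kmo_threshold: float = 0.5, bartlett_alpha: float = 0.05,
                 enforce_gates: bool = True):
        self.n_factors = n_factors
        self.rotation = rotation
        self.kmo_threshold = kmo_threshold
        self.bartlett_alpha = bartlett_alpha
        self.enforce_gates = enforce_gates

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = check_array(X)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        n, p = Xv.shape
        try:
            gates = kmo_bartlett(Xv)
            self.kmo_ = gates["kmo"]
            self.bartlett_p_ = gates["bartlett_p"]
        except ValueError:
            if self.enforce_gates:
                raise
            # tiny / collinear fitting tables have no defined KMO
            self.kmo_ = float("nan")
            self.bartlett_p_ = float("nan")
        if self.enforce_gates and not (self.kmo_ > self.kmo_threshold
                                       and self.bartlett_p_ < self.bartlett_alpha):
            raise ValueError(
                f"factorability gates failed (KMO={self.kmo_:.3f}, "
                f"Bartlett p={self.bartlett_p_:.3g})")

        self.mean_ = Xv.mean(axis=0)
        self.scale_ = Xv.std(axis=0, ddof=1)
        self.scale_[self.scale_ == 0] = 1.0  # constant column: leave centred
        Z = (Xv - self.mean_) / self.scale_
        R = np.corrcoef(Xv, rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.eigenvalues_all_ = evals
        k = int(np.sum(evals > 1.0)) if self.n_factors is None else int(self.n_factors)
        if k < 1:
            raise ValueError("no factor with eigenvalue > 1; nothing to retain")
        L = evecs[:, :k] * np.sqrt(evals[:k])
        if self.rotation == "varimax":
            L = varimax(L)
        elif self.rotation is not None:
            raise ValueError(f"unknown rotation '{self.rotation}'")
        # order factors by rotated explained variance, sign so loadings sum > 0
        ss = np.sum(L ** 2, axis=0)
        order = np.argsort(ss)[::-1]
        L = L[:, order]
        L *= np.sign(np.sum(L, axis=0) + 1e-300)
        self.loadings_ = L
        self.eigenvalues_ = np.sum(L ** 2, axis=0)
        self.explained_variance_ratio_ = float(np.sum(self.eigenvalues_) / p)
        self.n_factors_ = k
        # Thomson regression weights for factor scores on standardized data
        # (pinv tolerates the near-singular R of small fitting tables)
        self.score_coef_ = np.linalg.pinv(R) @ L
        self.feature_names_in_ = names
        self.n_features_in_ = p
        return self

    # -- application ------------------------------------------------------
    def _standardize(self, X) -> np.ndarray:
        if isinstance(X, FeatureVector):
            X = X.to_series().to_frame().T
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_in_ if f not in X.columns]
            if missing:
                raise ValueError(f"missing features: {missing}")
            Xv = X[self.feature_names_in_].to_numpy(dtype=float)
        else:
            Xv = check_array(X)
            if Xv.shape[1] != self.n_features_in_:
                raise ValueError("feature count mismatch")
        return (Xv - self.mean_) / self.scale_

    def transform(self, X) -> np.ndarray:
        """Regression-method factor scores, shape (n, n_factors_)."""
        check_is_fitted(self, "loadings_")
        return self._standardize(X) @ self.score_coef_

    def score_samples(self, X) -> np.ndarray:
        """Comprehensive score F = Σλ_iF_i / Σλ_i for each row; lower = more similar."""
        scores = self.transform(X)
        return scores @ self.eigenvalues_ / np.sum(self.eigenvalues_)

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "loadings_")
        return {
            "feature_names": list(self.feature_names_in_),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "eigenvalues_all": self.eigenvalues_all_.tolist(),
            "loadings": self.loadings_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "rotation": self.rotation,
            "score_coef": self.score_coef_.tolist(),
            "n_factors": self.n_factors_,
            "kmo": self.kmo_,
            "bartlett_p": self.bartlett_p_,
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ComprehensiveScoreModel":
        d = json.loads(Path(path).read_text())
        m = cls(n_factors=d["n_factors"], rotation=d["rotation"])
        m.feature_names_in_ = d["feature_names"]
        m.n_features_in_ = len(d["feature_names"])
        m.mean_ = np.array(d["mean"])
        m.scale_ = np.array(d["scale"])
        m.eigenvalues_all_ = np.array(d["eigenvalues_all"])
        m.loadings_ = np.array(d["loadings"])
        m.eigenvalues_ = np.array(d["eigenvalues"])
        m.n_factors_ = d["n_factors"]
        m.kmo_ = d["kmo"]
        m.bartlett_p_ = d["bartlett_p"]
        m.explained_variance_ratio_ = float(np.sum(m.eigenvalues_) / m.n_features_in_)
        m.score_coef_ = np.array(d["score_coef"])
        return m


def fit_factor_model(features: pd.DataFrame, **kwargs) -> ComprehensiveScoreModel:
    """Functional wrapper: fit a :class:`ComprehensiveScoreModel` on a table."""
    return ComprehensiveScoreModel(**kwargs).fit(features)


def comprehensive_score(model: ComprehensiveScoreModel, feature_vec) -> float:
    """Eigenvalue-weighted factor-score mean F of a single feature vector."""
    return float(model.score_samples(feature_vec)[0])


# ---------------------------------------------------------------------------
# Ordered-pair atlas cross-experiment
# ---------------------------------------------------------------------------

def pairwise_feature_table(atlas_db, config: RegistrationConfig | None = None
                           ) -> pd.DataFrame:
    """Features only (rigid alignment, no deformable stages) for every ordered pair.

    A cheap companion to :func:`pairwise_atlas_experiment` for fitting the
    comprehensive-score model when the dose-outcome columns are not needed.
    """
    atlas_db = list(atlas_db)
    config = config or RegistrationConfig()
    rows = []
    for new in atlas_db:
        for atlas in atlas_db:
            if atlas.id == new.id:
                continue
            rigid = register_rigid(new.image, atlas.image, config)
            fv = compute_feature_vector(new, atlas, rigid)
            row = {"new_id": new.id, "atlas_id": atlas.id}
            row.update(fv.to_series().to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def pairwise_atlas_experiment(atlas_db, config: RegistrationConfig | None = None,
                              oversample: int = 1) -> pd.DataFrame:
    """Leave-one-in cross prediction over every ordered atlas pair.

    Each case in turn plays the new patient while every other case serves as a
    single atlas: the full registration chain is run, the atlas dose warped and
    compared with the new case's own plan, and the 11 features recorded next to
    the 9 outcome metrics.  An n-case atlas yields n·(n−1) rows.  Failed
    registrations are logged and excluded rather than aborting the experiment.
    """
    atlas_db = list(atlas_db)
    if len(atlas_db) < 3:
        raise ValueError("need at least 3 atlas cases")
    for case in atlas_db:
        if not case.has_dose:
            raise ValueError(f"atlas case {case.id} has no dose")
    config = config or RegistrationConfig()
    rows = []
    for new in atlas_db:
        for atlas in atlas_db:
            if atlas.id == new.id:
                continue
            try:
                rigid = register_rigid(new.image, atlas.image, config)
                fv = compute_feature_vector(new, atlas, rigid)
                chain = build_chain(new, atlas, config)
                pred = warp_dose(atlas.dose, chain, new.image)
                rep = evaluate_case(pred, new, method="single_atlas",
                                    oversample=oversample)
            except Exception as err:  # noqa: BLE001 - row-level robustness
                warnings.warn(f"pair {atlas.id}->{new.id} failed and was "
                              f"excluded: {err}")
                continue
            row = {"new_id": new.id, "atlas_id": atlas.id}
            row.update(fv.to_series().to_dict())
            row.update(rep.to_series().to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
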