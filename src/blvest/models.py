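"""LASSO and random-forest blood-loss regressors under
leave-one-animal-out cross-validation.

Training data are observations from both the baseline (label 0 mL) and
the bleeding period (label = cumulative pumped volume at the window end).
Each subject's windows form one held-out fold; for group-normalized
models the normalization centers are refit on the training fold only and
then applied, unchanged, to the held-out subject.

Default hyperparameters: LASSO alpha = 0.05 for every modality; random
forest (n_estimators, max_depth) = (34, 12) for PPG, (15, 8) for ABP and
(43, 19) for the combined feature set.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso

from .features import design_matrix, modality_features
from .normalize import apply_center, fit_group_center, normalize_person

__all__ = [
    "ModelSpec",
    "CVResult",
    "DEFAULT_RF_PARAMS",
    "DEFAULT_LASSO_ALPHA",
    "make_estimator",
    "train",
    "loao_cv",
    "grid_search_rf",
    "rank_features",
]

DEFAULT_LASSO_ALPHA = 0.05
DEFAULT_RF_PARAMS = {
    "PPG": {"n_estimators": 34, "max_depth": 12},
    "ABP": {"n_estimators": 15, "max_depth": 8},
    "PPG&ABP": {"n_estimators": 43, "max_depth": 19},
}

METHODS = ("LASSO", "RF")
NORMALIZATIONS = ("person", "group", "none")


@dataclass(frozen=True)
class ModelSpec:
    """One model variant: method x modality x normalization scope."""

    method: str = "RF"
    modality: str = "PPG&ABP"
    normalization: str = "person"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    clip_zero: bool = False  # clamp negative BLV predictions; off so biases stay visible

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        modality_features(self.modality)  # validates

    def resolved_hyperparameters(self) -> dict:
        if self.method == "LASSO":
            return {"alpha": DEFAULT_LASSO_ALPHA, **self.hyperparameters}
        return {**DEFAULT_RF_PARAMS[self.modality], **self.hyperparameters}


@dataclass
class CVResult:
    """Out-of-fold predictions and per-fold importances of one variant."""

    spec: ModelSpec
    predictions: pd.DataFrame          # subject_id, start_s, phase, label_blv, predicted_blv
    fold_importances: pd.DataFrame     # index = held-out subject, columns = features
    fold_zero_counts: pd.Series | None  # LASSO only: zero coefficients per fold
    fold_train_hashes: dict[str, str] | None = None  # held-out subject -> sha256 of its training matrix

    @property
    def errors(self) -> pd.Series:
        """Estimation error, predicted minus reference (mL)."""
        return self.predictions["predicted_blv"] - self.predictions["label_blv"]


def make_estimator(spec: ModelSpec, seed: int | None = None):
    hp = spec.resolved_hyperparameters()
    seed = spec.seed if seed is None else seed
    if spec.method == "LASSO":
        return Lasso(alpha=hp["alpha"], max_iter=100_000, random_state=seed)
    return RandomForestRegressor(
        n_estimators=hp["n_estimators"],
        max_depth=hp["max_depth"],
        random_state=seed,
        n_jobs=1,
    )


def train(spec: ModelSpec, X: pd.DataFrame, y: np.ndarray | pd.Series, seed: int | None = None):
    """Fit one estimator; deterministic for a given (spec, seed)."""
    if len(X) == 0:
        raise ValueError("empty training set")
    Xv = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("training features contain non-finite values")
    est = make_estimator(spec, seed)
    est.fit(Xv, np.asarray(y, dtype=float))
    return est


def _importances(spec: ModelSpec, est) -> np.ndarray:
    if spec.method == "LASSO":
        return np.abs(est.coef_)
    return est.feature_importances_


def loao_cv(spec: ModelSpec, features: pd.DataFrame, collect_hashes: bool = False) -> CVResult:
    """Leave-one-animal-out cross-validation over a cohort feature frame.

    ``features`` is the wide frame from
    :func:`blvest.features.extract_cohort_features`.  For each subject j:
    fit the group normalizer (if requested) on the other subjects'
    baselines, normalize both sides, train on the others' windows
    (baseline and bleeding), and predict every usable window of j.
    Person normalization uses each subject's own baseline and therefore
    needs no per-fold refit.  One master seed spawns per-fold seeds.
    """
    X, meta = design_matrix(features, spec.modality)
    subjects = list(pd.unique(meta["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("leave-one-animal-out CV needs at least 2 subjects")

    if spec.normalization == "person":
        X = normalize_person(X, meta)

    fold_seeds = np.random.SeedSequence(spec.seed).generate_state(len(subjects)) & 0x7FFFFFFF
    preds = []
    importances = {}
    zero_counts = {}
    train_hashes: dict[str, str] = {}
    for j, sid in enumerate(subjects):
        test_idx = meta.index[meta["subject_id"] == sid]
        train_idx = meta.index[meta["subject_id"] != sid]
        if len(test_idx) == 0:
            warnings.warn(f"subject {sid} has no usable windows; skipped")
            continue
        X_tr, X_te = X.loc[train_idx], X.loc[test_idx]
        if spec.normalization == "group":
            center = fit_group_center(X, meta, [s for s in subjects if s != sid])
            X_tr = apply_center(center, X_tr)
            X_te = apply_center(center, X_te)
        if collect_hashes:
            payload = np.ascontiguousarray(
                np.column_stack(
                    [np.asarray(X_tr, dtype=float), meta.loc[train_idx, "label_blv"].to_numpy(float)]
                )
            )
            train_hashes[sid] = hashlib.sha256(payload.tobytes()).hexdigest()
        est = train(spec, X_tr, meta.loc[train_idx, "label_blv"], seed=int(fold_seeds[j]))
        yhat = est.predict(np.asarray(X_te, dtype=float))
        if spec.clip_zero:
            yhat = np.maximum(yhat, 0.0)
        fold = meta.loc[test_idx, ["subject_id", "start_s", "phase", "label_blv"]].copy()
        fold["predicted_blv"] = yhat
        preds.append(fold)
        imp = _importances(spec, est)
        importances[sid] = pd.Series(imp, index=X.columns)
        if spec.method == "LASSO":
            zero_counts[sid] = int(np.sum(est.coef_ == 0.0))

    return CVResult(
        spec=spec,
        predictions=pd.concat(preds, ignore_index=True),
        fold_importances=pd.DataFrame(importances).T,
        fold_zero_counts=pd.Series(zero_counts) if zero_counts else None,
        fold_train_hashes=train_hashes if collect_hashes else None,
    )


def rank_features(cv: CVResult) -> pd.DataFrame:
    """Mean importance across folds, ranked descending (rank 1 = top).

    LASSO importance is the mean absolute coefficient across folds; RF
    importance is the mean impurity-based importance.  For LASSO the
    per-fold zero-coefficient counts ride along in ``frame.attrs``.
    """
    mean_imp = cv.fold_importances.mean(axis=0)
    out = pd.DataFrame(
        {
            "feature": mean_imp.index,
            "importance": mean_imp.to_numpy(),
        }
    ).sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if cv.fold_zero_counts is not None:
        out.attrs["zero_coef_mean"] = float(cv.fold_zero_counts.mean())
        out.attrs["zero_coef_sd"] = float(cv.fold_zero_counts.std(ddof=1))
    return out


def grid_search_rf(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    n_estimators_grid,
    max_depth_grid,
    seed: int = 0,
) -> dict:
    """Exhaustive (n_estimators, max_depth) search with an inner
    leave-one-subject-out split and RMSE objective.

    Ties are broken toward the smaller model: fewer trees first, then a
    shallower depth, and the result is independent of grid ordering.
    """
    n_grid = sorted(set(int(v) for v in n_estimators_grid))
    d_grid = sorted(set(int(v) for v in max_depth_grid))
    if not n_grid or not d_grid:
        raise ValueError("grids must be nonempty")
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    gv = np.asarray(groups)
    uniq = pd.unique(gv)
    best = None
    for n_est in n_grid:
        for depth in d_grid:
            sq_err = []
            for g in uniq:
                tr = gv != g
                te = ~tr
                if tr.sum() == 0 or te.sum() == 0:
                    continue
                est = RandomForestRegressor(
                    n_estimators=n_est, max_depth=depth, random_state=seed, n_jobs=1
                )
                est.fit(Xv[tr], yv[tr])
                sq_err.append(np.mean((est.predict(Xv[te]) - yv[te]) ** 2))
            rmse = float(np.sqrt(np.mean(sq_err)))
            key = (rmse, n_est, depth)
            if best is None or key < best:
                best = key
    return {"n_estimators": best[1], "max_depth": best[2], "rmse": best[0]}
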