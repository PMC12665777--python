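"""Model validation battery.

Everything here takes a *fit spec* — either a scikit-learn-style estimator
(cloned per refit) or a callable ``fit_spec(X_train, y_train)`` returning an
object with ``.predict`` (or a bare predict callable).  Any feature
selection declared inside the fit spec is therefore re-run on every fold,
which is what keeps the cross-validation honest.

Implemented procedures: repeated k-fold cross-validation with empirical
quantiles, Y-randomization (label-permutation null for the training R²),
leave-cluster-out validation on k-means descriptor clusters, and split
conformal prediction intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cluster import KMeans
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "ModelMetrics",
    "ConformalModel",
    "ClusterFold",
    "ValidationReport",
    "metrics",
    "repeated_kfold",
    "y_randomization",
    "leave_cluster_out",
    "conformal_fit",
]


@dataclass(frozen=True)
class ModelMetrics:
    """R² (about the observed mean), RMSE and MAE for one prediction set."""

    r2: float
    rmse: float
    mae: float
    n: int


@dataclass
class ConformalModel:
    """Split conformal predictor: constant-width intervals ``ŷ ± q_hat``
    where ``q_hat`` is the ⌈(m+1)(1−α)⌉-th smallest absolute calibration
    residual (m calibration points)."""

    alpha: float
    q_hat: float
    n_calibration: int
    predict_fn: Callable[[pd.DataFrame], np.ndarray] | None = None

    def predict_interval(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.predict_fn is None:
            raise ValueError("no underlying predictor attached")
        pred = np.asarray(self.predict_fn(X), dtype=float)
        return pd.DataFrame({
            "prediction": pred,
            "lower": pred - self.q_hat,
            "upper": pred + self.q_hat,
        }, index=X.index if hasattr(X, "index") else None)


@dataclass(frozen=True)
class ClusterFold:
    """One held-out descriptor cluster in leave-cluster-out validation."""

    cluster: int
    n_train: int
    n_test: int
    r2: float
    rmse: float
    unstable: bool  # too few held-out points for a meaningful R²


@dataclass
class ValidationReport:
    """Aggregate of the validation battery (fields filled as computed)."""

    cv_r2_mean: float | None = None
    cv_r2_q025: float | None = None
    cv_r2_q975: float | None = None
    cv_rmse_mean: float | None = None
    cv_per_fold: list[dict] = field(default_factory=list)
    yrand_p: float | None = None
    lco_per_cluster: list[ClusterFold] = field(default_factory=list)
    conformal_coverage: float | None = None
    conformal_width: float | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "lco_per_cluster"}
        d["lco_per_cluster"] = [c.__dict__ for c in self.lco_per_cluster]
        return d


def metrics(y_obs: Sequence[float], y_pred: Sequence[float]) -> ModelMetrics:
    """R² = 1 − SSres/SStot (SStot about the observed mean), RMSE, MAE."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.size != y_pred.size:
        raise ValueError("y_obs and y_pred must have equal length")
    if y_obs.size < 2:
        raise ValueError("metrics require at least 2 observations")
    sstot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sstot <= 0:
        raise ValueError("R² undefined: zero variance in y_obs")
    ssres = float(np.sum((y_obs - y_pred) ** 2))
    return ModelMetrics(
        r2=1.0 - ssres / sstot,
        rmse=float(np.sqrt(np.mean((y_obs - y_pred) ** 2))),
        mae=float(np.mean(np.abs(y_obs - y_pred))),
        n=int(y_obs.size),
    )


def _fit_predictor(fit_spec, X: pd.DataFrame, y: np.ndarray) -> Callable[[pd.DataFrame], np.ndarray]:
    """Fit a fit-spec and return its predict callable."""
    if hasattr(fit_spec, "fit") and hasattr(fit_spec, "predict"):
        est = clone(fit_spec)
        est.fit(X, y)
        return lambda Xq: np.asarray(est.predict(Xq), dtype=float).ravel()
    fitted = fit_spec(X, y)
    if hasattr(fitted, "predict"):
        return lambda Xq: np.asarray(fitted.predict(Xq), dtype=float).ravel()
    return lambda Xq: np.asarray(fitted(Xq), dtype=float).ravel()


def _fold_indices(n: int, k: int, rng_seed: int) -> list[np.ndarray]:
    """Shuffled k-fold test-index lists; folds with < 2 points are merged
    into their neighbour (logged)."""
    kf = KFold(n_splits=min(k, n), shuffle=True, random_state=rng_seed)
    folds = [te for _, te in kf.split(np.arange(n))]
    merged: list[np.ndarray] = []
    for f in folds:
        if len(f) < 2 and merged:
            logger.info("repeated_kfold: merging a %d-point fold into its neighbour", len(f))
            merged[-1] = np.concatenate([merged[-1], f])
        else:
            merged.append(f)
    return merged


def repeated_kfold(fit_spec, X: pd.DataFrame, y: Sequence[float],
                   repeats: int = 10, k: int = 5, seed: int = 0) -> ValidationReport:
    """Repeated k-fold cross-validation.

    Each repeat draws a fresh seeded partition; the complete fit spec is
    re-fit on every fold's training rows.  Per-fold R²/RMSE (R² about the
    fold's observed mean) are pooled into a mean and empirical 2.5%/97.5%
    quantiles.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < k:
        raise ValueError(f"need n >= k (n={n}, k={k})")
    root = np.random.default_rng(seed)
    fold_r2: list[float] = []
    fold_rmse: list[float] = []
    detail: list[dict] = []
    for rep in range(repeats):
        rep_seed = int(root.integers(2**31 - 1))
        for fold_id, te in enumerate(_fold_indices(n, k, rep_seed)):
            tr = np.setdiff1d(np.arange(n), te)
            pred = _fit_predictor(fit_spec, X.iloc[tr], y[tr])(X.iloc[te])
            try:
                m = metrics(y[te], pred)
            except ValueError:  # zero-variance fold
                continue
            fold_r2.append(m.r2)
            fold_rmse.append(m.rmse)
            detail.append({"repeat": rep, "fold": fold_id, "r2": m.r2,
                           "rmse": m.rmse, "n_test": int(len(te))})
    r2 = np.array(fold_r2)
    rmse = np.array(fold_rmse)
    return ValidationReport(
        cv_r2_mean=float(r2.mean()),
        cv_r2_q025=float(np.quantile(r2, 0.025)),
        cv_r2_q975=float(np.quantile(r2, 0.975)),
        cv_rmse_mean=float(rmse.mean()),
        cv_per_fold=detail,
    )


def _train_r2(fit_spec, X: pd.DataFrame, y: np.ndarray) -> float:
    pred = _fit_predictor(fit_spec, X, y)(X)
    return metrics(y, pred).r2


def y_randomization(fit_spec, X: pd.DataFrame, y: Sequence[float],
                    B: int = 50, seed: int = 0) -> float:
    """Label-permutation null for the training R².

    Refits on B shuffles of ``y`` and returns the permutation-test p-value
    ``(1 + #{permuted R² ≥ observed R²}) / (B + 1)``; its minimum attainable
    value is ``1/(B+1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    observed = _train_r2(fit_spec, X, y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(y)
        if _train_r2(fit_spec, X, perm) >= observed:
            exceed += 1
    return (1 + exceed) / (B + 1)


def leave_cluster_out(fit_spec, X: pd.DataFrame, y: Sequence[float],
                      n_clusters: int = 4, seed: int = 0,
                      min_stable: int = 3) -> list[ClusterFold]:
    """Hold out whole k-means descriptor clusters in turn.

    Emulates prediction on a novel chemical neighbourhood.  Clusters with
    fewer than ``min_stable`` held-out points still get an R² (when defined)
    but are flagged ``unstable``.  An empty cluster triggers one re-seed
    attempt, then an error.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < n_clusters:
        raise ValueError(f"need n >= n_clusters (n={n}, k={n_clusters})")
    Xv = X.to_numpy(dtype=float)
    labels = None
    for attempt_seed in (seed, seed + 1):
        km = KMeans(n_clusters=n_clusters, random_state=attempt_seed, n_init=10)
        cand = km.fit_predict(Xv)
        if len(np.unique(cand)) == n_clusters:
            labels = cand
            break
    if labels is None:
        raise ValueError("leave_cluster_out: clustering produced an empty cluster")

    folds: list[ClusterFold] = []
    for c in range(n_clusters):
        te = np.flatnonzero(labels == c)
        tr = np.flatnonzero(labels != c)
        pred = _fit_predictor(fit_spec, X.iloc[tr], y[tr])(X.iloc[te])
        unstable = len(te) < min_stable
        try:
            m = metrics(y[te], pred)
            r2, rmse = m.r2, m.rmse
        except ValueError:
            r2 = float("nan")
            rmse = float(np.sqrt(np.mean((y[te] - pred) ** 2)))
            unstable = True
        folds.append(ClusterFold(cluster=c, n_train=len(tr), n_test=len(te),
                                 r2=r2, rmse=rmse, unstable=unstable))
    return folds


def conformal_fit(fit_spec, X_train: pd.DataFrame, y_train: Sequence[float],
                  alpha: float = 0.1, calib_fraction: float = 0.2,
                  seed: int = 0) -> ConformalModel:
    """Split conformal prediction.

    The training set is split into a proper-training part and a calibration
    part (default 80/20).  The model is fit on the proper-training rows and
    ``q_hat`` is the ⌈(m+1)(1−α)⌉-th smallest absolute calibration residual;
    when that rank exceeds m the interval is infinite (warned).
    """
    y = np.asarray(y_train, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    m = max(int(np.ceil(calib_fraction * n)), 1)
    calib, proper = perm[:m], perm[m:]
    if len(calib) < 5:
        raise ValueError(f"conformal_fit: calibration set too small ({len(calib)} < 5)")
    predict = _fit_predictor(fit_spec, X_train.iloc[proper], y[proper])
    resid = np.abs(y[calib] - predict(X_train.iloc[calib]))
    rank = int(np.ceil((m + 1) * (1 - alpha)))
    if rank > m:
        warnings.warn(
            f"calibration set of {m} cannot support alpha={alpha}; interval is infinite")
        q_hat = float("inf")
    else:
        q_hat = float(np.sort(resid)[rank - 1])
    return ConformalModel(alpha=alpha, q_hat=q_hat, n_calibration=m, predict_fn=predict)
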