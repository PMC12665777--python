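"""Regression models on standardized descriptors.

The core artifact is a named-coefficient multiple linear regression
(``y = β0 + Σ βj·xj`` on the standardized descriptor scale).  A partial
least squares model with cross-validated component count and tree-ensemble
baselines (random forest, gradient boosting) are provided for benchmarking.

The published eight-descriptor KRAS GA-MLR equation

    pIC50 = 6.6791 − 0.5139·TASA + 0.8145·RDFE14 + 0.6494·grav
            + 0.00898·RDFE19 + 0.3118·PNSA3 − 0.3224·RDFM11
            + 0.4943·RDFP9 − 0.4546·RDFV14

ships as a built-in reference model.  It expects descriptors already on its
training set's standardized scale; the original training mean/SD vector was
never published, so callers must standardize with their own statistics or
supply pre-standardized input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .preprocess import ScalingParams

logger = logging.getLogger(__name__)

__all__ = [
    "LinearModel",
    "PLSModel",
    "fit_ols",
    "predict",
    "published_kras_model",
    "fit_pls",
    "fit_baselines",
]

#: printed coefficients of the reference KRAS GA-MLR equation
KRAS_INTERCEPT = 6.6791
KRAS_COEFFICIENTS: dict[str, float] = {
    "TASA": -0.5139,
    "RDFE14": 0.8145,
    "grav": 0.6494,
    "RDFE19": 0.00898,
    "PNSA3": 0.3118,
    "RDFM11": -0.3224,
    "RDFP9": 0.4943,
    "RDFV14": -0.4546,
}


@dataclass(frozen=True)
class LinearModel:
    """Intercept + named coefficients on the standardized descriptor scale."""

    intercept: float
    coefficients: dict[str, float]
    scaling: ScalingParams | None = None
    n_train: int | None = None
    residual_sd: float | None = None
    method: str = "OLS"

    @property
    def p(self) -> int:
        return len(self.coefficients)

    def predict(self, X_std: pd.DataFrame | Mapping[str, Sequence[float]]) -> np.ndarray:
        """``β0 + Σ βj·xj`` per row; raises if any model descriptor is absent."""
        if not isinstance(X_std, pd.DataFrame):
            X_std = pd.DataFrame(X_std)
        missing = [c for c in self.coefficients if c not in X_std.columns]
        if missing:
            raise ValueError(f"predict: missing descriptor column(s): {missing}")
        names = list(self.coefficients)
        beta = np.array([self.coefficients[c] for c in names])
        return self.intercept + X_std[names].to_numpy(dtype=float) @ beta

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "n_train": self.n_train,
            "residual_sd": self.residual_sd,
        }
        if self.scaling is not None:
            payload["scaling"] = [
                {"column": c, "mean": float(m), "sd": float(s)}
                for c, m, s in zip(self.scaling.column_names,
                                   self.scaling.means, self.scaling.sds)
            ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        d = json.loads(Path(path).read_text())
        scaling = None
        if "scaling" in d:
            scaling = ScalingParams(
                column_names=tuple(e["column"] for e in d["scaling"]),
                means=np.array([e["mean"] for e in d["scaling"]]),
                sds=np.array([e["sd"] for e in d["scaling"]]),
            )
        return cls(intercept=float(d["intercept"]),
                   coefficients={k: float(v) for k, v in d["coefficients"].items()},
                   scaling=scaling, n_train=d.get("n_train"),
                   residual_sd=d.get("residual_sd"), method=d.get("method", "OLS"))


@dataclass
class PLSModel:
    """Fitted partial least squares regression with its CV-selected latent
    dimension and the per-component cross-validated RMSE curve."""

    n_components: int
    estimator: PLSRegression
    cv_rmse_per_component: np.ndarray
    column_names: tuple[str, ...] = field(default_factory=tuple)

    def predict(self, X_std: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(
            X_std[list(self.column_names)].to_numpy(dtype=float)).ravel()


def _dependent_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Identify columns not supporting full rank via pivoted QR."""
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[i] for i in sorted(piv[rank:])]


def fit_ols(X_train_std: pd.DataFrame, y_train: Sequence[float],
            scaling: ScalingParams | None = None) -> LinearModel:
    """Ordinary least squares on standardized descriptors via QR/lstsq.

    Requires n > p + 1 and a full-rank design; rank deficiency raises an
    error naming the dependent columns.  ``residual_sd`` uses the
    ``n − p − 1`` denominator.
    """
    y = np.asarray(y_train, dtype=float)
    X = X_train_std.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"fit_ols: need n > p+1 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        dep = _dependent_columns(design, ["(intercept)"] + list(X_train_std.columns))
        raise ValueError(f"fit_ols: rank-deficient design; dependent column(s): {dep}")
    resid = y - design @ coef
    residual_sd = float(np.sqrt(resid @ resid / (n - p - 1)))
    return LinearModel(
        intercept=float(coef[0]),
        coefficients={c: float(b) for c, b in zip(X_train_std.columns, coef[1:])},
        scaling=scaling, n_train=n, residual_sd=residual_sd, method="OLS",
    )


def predict(model: LinearModel, X_std: pd.DataFrame) -> np.ndarray:
    """Apply a linear model to standardized descriptors."""
    return model.predict(X_std)


def published_kras_model() -> LinearModel:
    """The built-in eight-descriptor KRAS GA-MLR reference equation.

    A pure constant: no fitted state, no scaling vector (the original
    training statistics were not published).
    """
    return LinearModel(intercept=KRAS_INTERCEPT,
                       coefficients=dict(KRAS_COEFFICIENTS),
                       method="GA-MLR (published)")


def fit_pls(X_train_std: pd.DataFrame, y_train: Sequence[float],
            max_components: int | None = None, cv_folds: int = 10,
            seed: int = 0) -> PLSModel:
    """PLS regression with the latent dimension chosen by k-fold CV RMSE.

    ``scale=False``: input is already standardized, and leaving it untouched
    preserves the exact full-rank equivalence with OLS.
    """
    y = np.asarray(y_train, dtype=float)
    X = X_train_std.to_numpy(dtype=float)
    n, p = X.shape
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if max_components is None:
        max_components = rank
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    max_components = min(max_components, rank)

    folds = min(cv_folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_rmse = np.zeros(max_components)
    for ncomp in range(1, max_components + 1):
        errs = []
        for tr, te in kf.split(X):
            m = PLSRegression(n_components=min(ncomp, np.linalg.matrix_rank(
                X[tr] - X[tr].mean(axis=0))), scale=False)
            m.fit(X[tr], y[tr])
            pred = m.predict(X[te]).ravel()
            errs.append((pred - y[te]) ** 2)
        cv_rmse[ncomp - 1] = float(np.sqrt(np.mean(np.concatenate(errs))))
    best = int(np.argmin(cv_rmse)) + 1
    est = PLSRegression(n_components=best, scale=False).fit(X, y)
    return PLSModel(n_components=best, estimator=est,
                    cv_rmse_per_component=cv_rmse,
                    column_names=tuple(X_train_std.columns))


def fit_baselines(X_train_std: pd.DataFrame, y_train: Sequence[float],
                  n_trees: int = 500, xgb_depth: int = 6, xgb_eta: float = 0.1,
                  xgb_rounds: int = 200, seed: int = 0) -> dict:
    """Reference tree-ensemble fits: random forest (500 trees) and gradient
    boosting (depth 6, learning rate 0.1, 200 rounds).

    Returns ``{"random_forest": {...}, "xgboost": {...}}``; each entry holds
    a fitted ``model`` plus training ``predictions``, or
    ``{"skipped": True, "reason": ...}`` when the optional dependency is
    absent.  These baselines inform comparative metrics and importance only —
    never the reference linear equation.
    """
    from sklearn.ensemble import RandomForestRegressor

    X = X_train_std.to_numpy(dtype=float)
    y = np.asarray(y_train, dtype=float)
    out: dict[str, dict] = {}

    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(X, y)
    out["random_forest"] = {"model": rf, "predictions": rf.predict(X)}

    try:
        from xgboost import XGBRegressor  # optional
    except ImportError:
        logger.info("fit_baselines: xgboost unavailable, skipping")
        out["xgboost"] = {"skipped": True, "reason": "xgboost not installed",
                          "predictions": None, "model": None}
        return out
    xgb = XGBRegressor(max_depth=xgb_depth, learning_rate=xgb_eta,
                       n_estimators=xgb_rounds, objective="reg:squarederror",
                       random_state=seed, verbosity=0)
    xgb.fit(X, y)
    out["xgboost"] = {"model": xgb, "predictions": xgb.predict(X)}
    return out
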