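"""Applicability-domain assessment.

Two complementary views of whether a prediction is an extrapolation:

* **Mahalanobis**: squared distance ``D² = (x−μ)ᵀ Σ⁻¹ (x−μ)`` from the
  training centroid, with μ and Σ the training mean and sample covariance.
  For Gaussian descriptors D² is asymptotically χ²(p), so the default
  cutoff is the 95th percentile of χ² with p degrees of freedom; a fixed
  cutoff (e.g. 15.0) is supported for reproducing published screening flags.
* **Williams**: leverage ``h_i = x̃_i (X̃ᵀX̃)⁻¹ x̃_iᵀ`` on the
  intercept-augmented training design, against the conventional warning
  threshold ``h* = 3(p+1)/n``, combined with standardized residuals within
  ±3 where observed activities exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .validate import ModelMetrics, metrics

logger = logging.getLogger(__name__)

__all__ = [
    "ADReport",
    "MahalanobisDomain",
    "mahalanobis_doa",
    "williams_ad",
    "williams_threshold",
    "ad_stratified_metrics",
]


@dataclass
class ADReport:
    """Per-compound applicability-domain table plus global thresholds."""

    table: pd.DataFrame
    md_threshold: float | None = None
    h_star: float | None = None
    coverage_train: float | None = None
    coverage_test: float | None = None
    extras: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="id")

    def globals_dict(self) -> dict:
        return {
            "md_threshold": self.md_threshold,
            "h_star": self.h_star,
            "coverage_train": self.coverage_train,
            "coverage_test": self.coverage_test,
            **self.extras,
        }


class MahalanobisDomain(BaseEstimator):
    """Mahalanobis-distance applicability domain.

    Parameters
    ----------
    threshold : float, optional
        Fixed D² cutoff; overrides the analytic χ² quantile.
    df : int, optional
        Degrees of freedom for the χ² quantile (default: number of columns).
    quantile : float
        χ² probability level for the analytic cutoff.
    ridge_eps : float
        Relative ridge added to a singular covariance (logged).
    """

    def __init__(self, threshold: float | None = None, df: int | None = None,
                 quantile: float = 0.95, ridge_eps: float = 1e-8):
        self.threshold = threshold
        self.df = df
        self.quantile = quantile
        self.ridge_eps = ridge_eps

    def fit(self, X_train_std: pd.DataFrame, y=None) -> "MahalanobisDomain":
        X = X_train_std.to_numpy(dtype=float)
        self.columns_ = tuple(X_train_std.columns)
        self.mean_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        try:
            self.precision_ = np.linalg.inv(cov)
            # reject numerically garbage inverses of near-singular matrices
            if not np.all(np.isfinite(self.precision_)) or np.linalg.cond(cov) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            eps = self.ridge_eps * float(np.mean(np.diag(cov)))
            logger.info("MahalanobisDomain: singular covariance, adding ridge %g", eps)
            self.precision_ = np.linalg.inv(cov + eps * np.eye(cov.shape[0]))
        df = self.df if self.df is not None else X.shape[1]
        self.threshold_ = (float(self.threshold) if self.threshold is not None
                           else float(chi2.ppf(self.quantile, df)))
        return self

    def score_samples(self, X_query_std: pd.DataFrame) -> np.ndarray:
        """Squared Mahalanobis distance per query row."""
        missing = [c for c in self.columns_ if c not in X_query_std.columns]
        if missing:
            raise ValueError(f"query matrix missing column(s): {missing}")
        Xq = X_query_std[list(self.columns_)].to_numpy(dtype=float)
        diff = Xq - self.mean_
        return np.einsum("ij,jk,ik->i", diff, self.precision_, diff)

    def predict(self, X_query_std: pd.DataFrame) -> np.ndarray:
        """Boolean inside-domain flags (D² ≤ threshold)."""
        return self.score_samples(X_query_std) <= self.threshold_


def mahalanobis_doa(X_train_std: pd.DataFrame, X_query_std: pd.DataFrame,
                    df_override: int | None = None,
                    threshold_override: float | None = None) -> ADReport:
    """Mahalanobis-distance domain assessment of a query set."""
    dom = MahalanobisDomain(threshold=threshold_override, df=df_override)
    dom.fit(X_train_std)
    d2 = dom.score_samples(X_query_std)
    table = pd.DataFrame({
        "mahalanobis_d2": d2,
        "inside_md": d2 <= dom.threshold_,
    }, index=X_query_std.index)
    return ADReport(table=table, md_threshold=dom.threshold_)


def williams_threshold(p: int, n: int) -> float:
    """Conventional leverage warning threshold ``h* = 3(p+1)/n``."""
    if n < 1 or p < 0:
        raise ValueError("need n >= 1 and p >= 0")
    return 3.0 * (p + 1) / n


def williams_ad(X_train_std: pd.DataFrame, X_test_std: pd.DataFrame | None,
                residuals_train: Sequence[float],
                residuals_test: Sequence[float] | None = None,
                residual_scale: float | None = None) -> ADReport:
    """Williams-plot applicability domain (leverage vs standardized residual).

    Leverages come from the intercept-augmented training design's projector;
    test leverages use the same projector.  A point is inside when
    ``h ≤ h* = 3(p+1)/n`` and ``|standardized residual| ≤ 3``.
    ``residual_scale`` defaults to the training residual SD with an
    ``n − p − 1`` denominator.
    """
    Xtr = X_train_std.to_numpy(dtype=float)
    n, p = Xtr.shape
    design = np.column_stack([np.ones(n), Xtr])
    gram = design.T @ design
    if np.linalg.matrix_rank(gram) < p + 1:
        raise ValueError("williams_ad: rank-deficient training design")
    ginv = np.linalg.inv(gram)

    def leverages(X: np.ndarray) -> np.ndarray:
        D = np.column_stack([np.ones(X.shape[0]), X])
        return np.einsum("ij,jk,ik->i", D, ginv, D)

    rtr = np.asarray(residuals_train, dtype=float)
    if rtr.size != n:
        raise ValueError("residuals_train length mismatch")
    if residual_scale is None:
        if n - p - 1 < 1:
            raise ValueError("cannot estimate residual scale: n - p - 1 < 1")
        residual_scale = float(np.sqrt(rtr @ rtr / (n - p - 1)))
    h_star = williams_threshold(p, n)

    frames = []
    h_tr = leverages(Xtr)
    std_tr = rtr / residual_scale
    frames.append(pd.DataFrame({
        "leverage": h_tr, "std_residual": std_tr,
        "inside_williams": (h_tr <= h_star) & (np.abs(std_tr) <= 3),
        "set": "train",
    }, index=X_train_std.index))
    coverage_test = None
    if X_test_std is not None:
        Xte = X_test_std[list(X_train_std.columns)].to_numpy(dtype=float)
        h_te = leverages(Xte)
        if residuals_test is not None:
            std_te = np.asarray(residuals_test, dtype=float) / residual_scale
        else:
            std_te = np.full(Xte.shape[0], np.nan)
        inside_te = (h_te <= h_star) & (np.abs(np.nan_to_num(std_te)) <= 3)
        frames.append(pd.DataFrame({
            "leverage": h_te, "std_residual": std_te,
            "inside_williams": inside_te, "set": "test",
        }, index=X_test_std.index))
        coverage_test = float(inside_te.mean())
    table = pd.concat(frames)
    return ADReport(
        table=table, h_star=h_star,
        coverage_train=float(frames[0]["inside_williams"].mean()),
        coverage_test=coverage_test,
        extras={"residual_scale": residual_scale},
    )


def ad_stratified_metrics(y_obs: Sequence[float], y_pred: Sequence[float],
                          inside_flags: Sequence[bool], min_n: int = 3) -> dict:
    """Fit metrics for the full set and the inside/outside-domain strata.

    Strata with fewer than ``min_n`` points report their count only (metrics
    suppressed), matching how sparse outside-domain strata are usually
    tabulated.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    flags = np.asarray(inside_flags, dtype=bool)
    if not (y_obs.size == y_pred.size == flags.size):
        raise ValueError("inputs must have equal length")

    def stratum(mask: np.ndarray) -> dict:
        k = int(mask.sum())
        if k < min_n:
            return {"n": k, "metrics": None}
        try:
            m = metrics(y_obs[mask], y_pred[mask])
        except ValueError:
            return {"n": k, "metrics": None}
        return {"n": k, "metrics": m}

    return {
        "all": stratum(np.ones_like(flags, dtype=bool)),
        "inside": stratum(flags),
        "outside": stratum(~flags),
    }
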