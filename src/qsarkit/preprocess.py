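"""Descriptor preprocessing: standardization, redundancy filters, splitting.

The pipeline order is fixed: drop columns with missing values (done at
ingestion), drop zero-variance columns, remove one member of every descriptor
pair with |Pearson r| above the cutoff, keep the top-k columns by variance on
the original (pre-scaling) scale, then re-estimate standardization on the
survivors and split into stratified training/test sets.  Variance ranking is
only meaningful before scaling — after unit-variance scaling every column
ties — so the top-k step uses raw variances even though correlation filtering
(scale-free) and modelling operate on the standardized scale.

All transformers follow the scikit-learn estimator contract (``fit`` /
``transform``, fitted attributes with trailing underscores) and operate on
pandas DataFrames so descriptor names survive every step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingParams",
    "SplitResult",
    "Standardizer",
    "CorrelationFilter",
    "VarianceTopK",
    "standardize",
    "apply_scaling",
    "correlation_filter",
    "variance_topk",
    "stratified_split",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class ScalingParams:
    """Per-column training mean and sample SD (ddof=1) used to place new
    compounds in the model's standardized descriptor space."""

    column_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        if not (len(self.column_names) == means.size == sds.size):
            raise ValueError("ScalingParams: inconsistent lengths")
        if not np.all(sds > 0):
            raise ValueError("ScalingParams: SDs must be strictly positive")

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"column": c, "mean": float(m), "sd": float(s)}
            for c, m, s in zip(self.column_names, self.means, self.sds)
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            column_names=tuple(e["column"] for e in payload),
            means=np.array([e["mean"] for e in payload]),
            sds=np.array([e["sd"] for e in payload]),
        )


@dataclass(frozen=True)
class SplitResult:
    """A stratified train/test partition of compound ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    train_fraction: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("SplitResult: train and test ids overlap")


class Standardizer(BaseEstimator, TransformerMixin):
    """Center to the mean and scale to unit sample variance (ddof=1).

    Zero-variance columns are dropped at fit time and logged.  Fitted
    attributes: ``params_`` (:class:`ScalingParams`), ``dropped_``.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "Standardizer":
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("standardize requires at least 2 rows")
        sds = X.std(ddof=1)
        dropped = [c for c in X.columns if not sds[c] > 0]
        if dropped:
            logger.info("Standardizer: dropping %d zero-variance column(s): %s",
                        len(dropped), dropped)
        kept = [c for c in X.columns if c not in dropped]
        if not kept:
            raise ValueError("standardize: every column has zero variance")
        self.dropped_ = tuple(dropped)
        self.params_ = ScalingParams(
            column_names=tuple(kept),
            means=X[kept].mean().to_numpy(),
            sds=X[kept].std(ddof=1).to_numpy(),
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return apply_scaling(_as_frame(X), self.params_)


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Drop the later column of every pair with |Pearson r| > ``r_max``.

    The scan is greedy in column order: a column is kept only if its absolute
    correlation with every previously kept column is within the cutoff, so of
    an offending pair the earlier column always survives.
    """

    def __init__(self, r_max: float = 0.95):
        self.r_max = r_max

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationFilter":
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("correlation filter requires at least 2 rows")
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
        corr = np.atleast_2d(corr)
        cols = list(X.columns)
        kept_idx: list[int] = []
        dropped: list[str] = []
        for j in range(len(cols)):
            if any(abs(corr[i, j]) > self.r_max for i in kept_idx):
                dropped.append(cols[j])
            else:
                kept_idx.append(j)
        if dropped:
            logger.info("CorrelationFilter: dropped %d column(s) with |r| > %g: %s",
                        len(dropped), self.r_max, dropped)
        self.keep_columns_ = tuple(cols[i] for i in kept_idx)
        self.dropped_ = tuple(dropped)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return _as_frame(X)[list(self.keep_columns_)]


class VarianceTopK(BaseEstimator, TransformerMixin):
    """Keep the ``k`` columns of largest sample variance (ddof=1), preserving
    original column order; ties at the k-th variance favour the earlier
    column.  Identity when the matrix has at most ``k`` columns."""

    def __init__(self, k: int = 50):
        self.k = k

    def fit(self, X: pd.DataFrame, y=None) -> "VarianceTopK":
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X = _as_frame(X)
        cols = list(X.columns)
        if len(cols) <= self.k:
            self.keep_columns_ = tuple(cols)
            return self
        variances = X.var(ddof=1).to_numpy()
        # stable sort on -variance: equal variances resolve to the earlier column
        ranked = np.argsort(-variances, kind="stable")[: self.k]
        keep = sorted(ranked)
        self.keep_columns_ = tuple(cols[i] for i in keep)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return _as_frame(X)[list(self.keep_columns_)]


def _as_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("descriptor matrices must be pandas DataFrames with named columns")
    return X


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Standardize a descriptor matrix; returns the scaled matrix and the
    training statistics needed to place future compounds on the same scale."""
    est = Standardizer().fit(X)
    return est.transform(X), est.params_


def apply_scaling(X: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Apply stored training mean/SD scaling to ``X``.

    Columns not named in ``params`` are dropped (logged); a missing required
    column is an error listing the absent names.  Output column order follows
    ``params``.
    """
    X = _as_frame(X)
    missing = [c for c in params.column_names if c not in X.columns]
    if missing:
        raise ValueError(f"apply_scaling: missing required column(s): {missing}")
    extra = [c for c in X.columns if c not in params.column_names]
    if extra:
        logger.info("apply_scaling: ignoring %d extra column(s): %s", len(extra), extra)
    vals = X[list(params.column_names)].to_numpy(dtype=float)
    scaled = (vals - params.means) / params.sds
    return pd.DataFrame(scaled, index=X.index, columns=list(params.column_names))


def correlation_filter(X: pd.DataFrame, r_max: float = 0.95) -> pd.DataFrame:
    """Remove highly correlated descriptors (greedy, keep-earlier rule)."""
    return CorrelationFilter(r_max=r_max).fit_transform(X)


def variance_topk(X: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Keep the k highest-variance descriptors (pre-scaling variances)."""
    return VarianceTopK(k=k).fit_transform(X)


def stratified_split(
    ids: Sequence[str],
    y: Sequence[float],
    train_fraction: float = 0.7,
    n_bins: int = 5,
    seed: int = 0,
) -> SplitResult:
    """Stratified train/test split on a continuous response.

    ``y`` is cut into ``n_bins`` quantile bins.  Per-bin training counts are
    allocated by the largest-remainder rule so the total equals
    ``round(train_fraction * n)`` exactly (ties broken by bin order); bin
    membership is then sampled without replacement with a generator seeded
    by ``seed``.
    """
    ids = [str(i) for i in ids]
    y = np.asarray(y, dtype=float)
    if len(ids) != y.size:
        raise ValueError("ids and y must have equal length")
    if y.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples, got {y.size}")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")

    bins = pd.qcut(y, q=n_bins, labels=False, duplicates="drop")
    uniq = np.unique(bins)
    sizes = np.array([int(np.sum(bins == b)) for b in uniq])
    target = int(round(train_fraction * y.size))
    quota = train_fraction * sizes
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    short = target - int(alloc.sum())
    if short > 0:
        # stable sort: equal remainders favour earlier bins
        for i in np.argsort(-remainder, kind="stable")[:short]:
            alloc[i] += 1
    alloc = np.minimum(alloc, sizes)

    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for b, n_train in zip(uniq, alloc):
        members = [ids[i] for i in np.flatnonzero(bins == b)]
        chosen = set(rng.choice(len(members), size=int(n_train), replace=False).tolist())
        for i, cid in enumerate(members):
            (train if i in chosen else test).append(cid)
    return SplitResult(
        train_ids=tuple(train), test_ids=tuple(test),
        seed=int(seed), train_fraction=float(train_fraction),
    )


def preprocess_pipeline(
    X: pd.DataFrame,
    y: pd.Series,
    r_max: float = 0.95,
    top_k: int = 50,
    train_fraction: float = 0.7,
    n_bins: int = 5,
    seed: int = 0,
) -> dict:
    """Run the full reduction chain and split.

    Steps (logged): zero-variance drop -> correlation filter -> top-k variance
    -> standardize survivors on the training rows -> stratified split.  The
    scaling statistics come from the training rows only, and the test matrix
    is placed on that scale, mirroring how future screening compounds are
    treated.

    Returns a dict with keys ``X_train`` / ``X_test`` (standardized),
    ``y_train`` / ``y_test``, ``scaling`` and ``split``.
    """
    logger.info("preprocess order: drop-zero-variance -> correlation_filter(r_max=%g) "
                "-> variance_topk(k=%d) -> standardize -> stratified_split", r_max, top_k)
    sds = X.std(ddof=1)
    zero_var = [c for c in X.columns if not sds[c] > 0]
    if zero_var:
        logger.info("dropping %d zero-variance column(s)", len(zero_var))
        X = X.drop(columns=zero_var)
    X = correlation_filter(X, r_max=r_max)
    X = variance_topk(X, k=top_k)

    split = stratified_split(list(X.index), y.loc[X.index].to_numpy(),
                             train_fraction=train_fraction, n_bins=n_bins, seed=seed)
    X_train_raw = X.loc[list(split.train_ids)]
    X_test_raw = X.loc[list(split.test_ids)]
    X_train, scaling = standardize(X_train_raw)
    X_test = apply_scaling(X_test_raw, scaling)
    return {
        "X_train": X_train,
        "X_test": X_test,
        "y_train": y.loc[list(split.train_ids)],
        "y_test": y.loc[list(split.test_ids)],
        "scaling": scaling,
        "split": split,
    }
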