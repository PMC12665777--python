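"""Virtual screening of candidate compounds.

Raw query descriptors are placed on the model's standardized scale using the
*training* mean/SD, scored with the linear model, optionally wrapped in split
conformal intervals, and flagged against the Mahalanobis applicability
domain.  A hit is a compound whose predicted pIC50 strictly exceeds the
potency threshold (default 8.0); outside-domain compounds keep their
predictions but are labelled extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain import MahalanobisDomain
from .models import LinearModel
from .preprocess import ScalingParams, apply_scaling
from .validate import ConformalModel

__all__ = ["ScreeningResult", "screen", "summarize_hits"]


@dataclass
class ScreeningResult:
    """Per-compound screening table plus global counts."""

    table: pd.DataFrame  # pic50_pred, interval_low/high, mahalanobis_d2, inside_doa, is_hit
    hit_threshold: float
    n_inside: int
    n_outside: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="id")


def screen(model: LinearModel, scaling: ScalingParams, X_query_raw: pd.DataFrame,
           conformal: ConformalModel | None = None,
           domain: MahalanobisDomain | None = None,
           hit_threshold: float = 8.0) -> ScreeningResult:
    """Score a raw-scale query descriptor matrix.

    Pipeline: apply training scaling → predict → optional conformal interval
    → optional Mahalanobis flags → strict-inequality hit calls.  A missing
    model descriptor raises before any prediction.  Pure function of its
    inputs: neither the model nor the scaling is mutated.
    """
    missing = [c for c in model.coefficients if c not in X_query_raw.columns]
    if missing:
        raise ValueError(f"screen: query matrix missing descriptor(s): {missing}")
    X_std = apply_scaling(X_query_raw, scaling)
    pred = model.predict(X_std)

    if conformal is not None and np.isfinite(conformal.q_hat):
        lo, hi = pred - conformal.q_hat, pred + conformal.q_hat
    else:
        lo = np.full_like(pred, -np.inf) if conformal is not None else np.full_like(pred, np.nan)
        hi = np.full_like(pred, np.inf) if conformal is not None else np.full_like(pred, np.nan)

    if domain is not None:
        d2 = domain.score_samples(X_std)
        inside = d2 <= domain.threshold_
    else:
        d2 = np.full_like(pred, np.nan)
        inside = np.ones(pred.size, dtype=bool)

    table = pd.DataFrame({
        "pic50_pred": pred,
        "interval_low": lo,
        "interval_high": hi,
        "mahalanobis_d2": d2,
        "inside_doa": inside,
        "is_hit": pred > hit_threshold,
    }, index=X_query_raw.index)
    return ScreeningResult(
        table=table, hit_threshold=float(hit_threshold),
        n_inside=int(inside.sum()), n_outside=int((~inside).sum()),
    )


def summarize_hits(result: ScreeningResult) -> dict:
    """Hit triage summary.

    Hits sorted by predicted pIC50 descending (ties by id); the *reliable*
    subset is hits that are also inside the applicability domain.
    """
    t = result.table
    hits = t[t["is_hit"]].copy()
    if len(hits):
        order = np.lexsort((hits.index.astype(str), -hits["pic50_pred"].to_numpy()))
        hits = hits.iloc[order]
    reliable = hits[hits["inside_doa"]]
    return {
        "hit_threshold": result.hit_threshold,
        "n_screened": int(len(t)),
        "n_hits": int(len(hits)),
        "n_hits_inside": int(len(reliable)),
        "n_hits_outside": int(len(hits) - len(reliable)),
        "hits": [{"id": str(i), "pic50_pred": float(r.pic50_pred),
                  "inside_doa": bool(r.inside_doa)} for i, r in hits.iterrows()],
        "reliable_hits": [str(i) for i in reliable.index],
        "n_inside": result.n_inside,
        "n_outside": result.n_outside,
    }
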