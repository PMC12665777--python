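"""Descriptor-subset selection.

Four strategies over a standardized training matrix:

* a binary genetic algorithm maximizing a complexity-penalized adjusted R²,
  ``fitness = R²_adj − k/n`` with k the number of selected descriptors and n
  the number of training samples;
* bidirectional stepwise search on the Akaike information criterion;
* a BIC-penalized greedy refit restricted to a previously selected pool;
* iterative variance-inflation-factor screening for multicollinearity.

The GA uses tournament selection (size 2), uniform crossover, per-bit
mutation (default rate 1/p), and one elite chromosome, so its best-fitness
trace is non-decreasing.  It stops after ``max_generations`` generations or
once ``patience`` consecutive generations pass without best-fitness
improvement.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.outliers_influence import variance_inflation_factor

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "SelectionResult",
    "GASelector",
    "adjusted_r2",
    "ga_fitness",
    "ga_select",
    "vif_filter",
    "stepwise_aic",
    "bic_refit",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (defaults follow the study protocol:
    50 generations with a 10-generation no-improvement stop)."""

    population_size: int = 50
    max_generations: int = 50
    patience: int = 10
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # None -> 1/p
    tournament_size: int = 2
    n_elite: int = 1
    init_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 1 or self.patience < 1:
            raise ValueError("max_generations and patience must be >= 1")
        for name in ("crossover_rate", "init_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a subset search: boolean mask over the candidate columns,
    the criterion value attained, and the per-step trace."""

    mask: np.ndarray
    column_names: tuple[str, ...]
    fitness: float
    history: tuple[float, ...]
    method: str

    @property
    def selected_names(self) -> tuple[str, ...]:
        return tuple(c for c, m in zip(self.column_names, self.mask) if m)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "method": self.method,
            "selected": list(self.selected_names),
            "candidates": list(self.column_names),
            "fitness": self.fitness,
            "history": list(self.history),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        selected = set(d["selected"])
        cols = tuple(d["candidates"])
        return cls(
            mask=np.array([c in selected for c in cols]),
            column_names=cols,
            fitness=float(d["fitness"]),
            history=tuple(d["history"]),
            method=d["method"],
        )


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted coefficient of determination,
    ``1 - (1 - R²)(n - 1)/(n - k - 1)``."""
    if n - k - 1 < 1:
        raise ValueError(f"adjusted R² undefined for n={n}, k={k} (n-k-1 < 1)")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _ols_r2(Xs: np.ndarray, y: np.ndarray) -> float | None:
    """Training R² of an intercept-augmented least-squares fit; None when the
    design is rank deficient."""
    n, k = Xs.shape
    design = np.column_stack([np.ones(n), Xs])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k + 1:
        return None
    resid = y - design @ coef
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot <= 0:
        return None
    return 1.0 - float(resid @ resid) / sstot


def ga_fitness(mask: Sequence[bool], X_train: pd.DataFrame, y_train: Sequence[float]) -> float:
    """Penalized fitness ``R²_adj − k/n`` of an OLS fit on the masked columns.

    Degenerate masks (empty, too large for the adjusted-R² denominator, or
    rank-deficient designs) return ``-inf`` so the GA can discard them without
    special-casing.
    """
    mask = np.asarray(mask, dtype=bool)
    X = X_train.to_numpy(dtype=float)
    y = np.asarray(y_train, dtype=float)
    n = X.shape[0]
    k = int(mask.sum())
    if k == 0 or n - k - 1 < 1:
        return _NEG_INF
    r2 = _ols_r2(X[:, mask], y)
    if r2 is None:
        return _NEG_INF
    return adjusted_r2(r2, n, k) - k / n


class GASelector(BaseEstimator):
    """Elitist generational GA over binary descriptor masks.

    Parameters mirror :class:`GAConfig`; fitted attributes are ``support_``
    (boolean mask), ``fitness_``, ``history_`` (best fitness per generation,
    non-decreasing) and ``column_names_``.
    """

    def __init__(self, population_size: int = 50, max_generations: int = 50,
                 patience: int = 10, crossover_rate: float = 0.9,
                 mutation_rate: float | None = None, tournament_size: int = 2,
                 n_elite: int = 1, init_prob: float = 0.3, seed: int = 0):
        self.population_size = population_size
        self.max_generations = max_generations
        self.patience = patience
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.tournament_size = tournament_size
        self.n_elite = n_elite
        self.init_prob = init_prob
        self.seed = seed

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size, max_generations=self.max_generations,
            patience=self.patience, crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate, tournament_size=self.tournament_size,
            n_elite=self.n_elite, init_prob=self.init_prob, seed=self.seed,
        )

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "GASelector":
        cfg = self._config()  # validates
        Xv = X.to_numpy(dtype=float)
        yv = np.asarray(y, dtype=float)
        n, p = Xv.shape
        rng = np.random.default_rng(cfg.seed)
        mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / p

        cache: dict[bytes, float] = {}

        def fitness(mask: np.ndarray) -> float:
            key = np.packbits(mask).tobytes()
            if key not in cache:
                cache[key] = ga_fitness(mask, X, yv)
            return cache[key]

        pop = rng.random((cfg.population_size, p)) < cfg.init_prob
        # guarantee at least one active bit per chromosome
        for row in pop:
            if not row.any():
                row[rng.integers(p)] = True

        fits = np.array([fitness(m) for m in pop])
        history: list[float] = []
        best_idx = int(np.argmax(fits))
        best_mask, best_fit = pop[best_idx].copy(), float(fits[best_idx])
        stall = 0

        for _ in range(cfg.max_generations):
            order = np.argsort(-fits, kind="stable")
            elite = [pop[i].copy() for i in order[: cfg.n_elite]]
            children: list[np.ndarray] = list(elite)
            while len(children) < cfg.population_size:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(cfg.population_size, size=cfg.tournament_size)
                    winner = contenders[int(np.argmax(fits[contenders]))]
                    parents.append(pop[winner])
                c1, c2 = parents[0].copy(), parents[1].copy()
                if rng.random() < cfg.crossover_rate:
                    swap = rng.random(p) < 0.5
                    c1[swap], c2[swap] = parents[1][swap], parents[0][swap]
                for child in (c1, c2):
                    flip = rng.random(p) < mut
                    child[flip] = ~child[flip]
                    if len(children) < cfg.population_size:
                        children.append(child)
            pop = np.array(children)
            fits = np.array([fitness(m) for m in pop])

            gen_best = int(np.argmax(fits))
            if fits[gen_best] > best_fit + 1e-12:
                best_fit = float(fits[gen_best])
                best_mask = pop[gen_best].copy()
                stall = 0
            else:
                stall += 1
            history.append(best_fit)
            if stall >= cfg.patience:
                break

        self.column_names_ = tuple(X.columns)
        self.support_ = best_mask
        self.fitness_ = best_fit
        self.history_ = tuple(history)
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[[c for c, m in zip(self.column_names_, self.support_) if m]]

    def result_(self) -> SelectionResult:
        return SelectionResult(
            mask=self.support_.copy(), column_names=self.column_names_,
            fitness=self.fitness_, history=self.history_, method="GA",
        )


def ga_select(X_train: pd.DataFrame, y_train: Sequence[float],
              config: GAConfig | None = None) -> SelectionResult:
    """Run the genetic algorithm and return a :class:`SelectionResult`."""
    cfg = config or GAConfig()
    sel = GASelector(**{f: getattr(cfg, f) for f in (
        "population_size", "max_generations", "patience", "crossover_rate",
        "mutation_rate", "tournament_size", "n_elite", "init_prob", "seed")})
    sel.fit(X_train, y_train)
    return sel.result_()


def vif_filter(X: pd.DataFrame, vif_max: float = 10.0) -> SelectionResult:
    """Iteratively remove the column with the largest variance inflation
    factor until every VIF is at most ``vif_max``.

    VIF_j = 1/(1 − R²_j) with R²_j from regressing column j on the remaining
    columns.  Perfectly collinear columns have infinite VIF and are removed
    first; ties resolve to the later column.  A single surviving column stops
    the iteration (its VIF is 1 by convention).
    """
    if X.shape[1] < 1:
        raise ValueError("vif_filter requires at least one column")
    cols = list(X.columns)
    kept = list(cols)
    trace: list[float] = []
    while len(kept) > 1:
        arr = X[kept].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([variance_inflation_factor(arr, j) for j in range(len(kept))])
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        worst = np.max(vifs)
        if worst <= vif_max:
            trace.append(float(worst))
            break
        # ties -> remove the later column
        drop_idx = int(np.flatnonzero(vifs == worst)[-1])
        logger.info("vif_filter: removing %r (VIF=%.3g)", kept[drop_idx], worst)
        trace.append(float(worst))
        kept.pop(drop_idx)
    mask = np.array([c in kept for c in cols])
    final = float(trace[-1]) if trace else 1.0
    return SelectionResult(mask=mask, column_names=tuple(cols),
                           fitness=final, history=tuple(trace), method="VIF")


def _ic(Xs: np.ndarray, y: np.ndarray, penalty: float) -> float:
    """Gaussian concentrated-likelihood information criterion
    ``n·ln(RSS/n) + penalty·(k+1)`` (additive constants dropped)."""
    n = y.size
    k = Xs.shape[1] if Xs.ndim == 2 else 0
    design = np.column_stack([np.ones(n)] + ([Xs] if k else []))
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return math.inf
    resid = y - design @ coef
    rss = max(float(resid @ resid), 1e-300)
    return n * math.log(rss / n) + penalty * (k + 1)


def _greedy_bidirectional(X: pd.DataFrame, y: Sequence[float], penalty: float,
                          pool: Sequence[str], method: str) -> SelectionResult:
    yv = np.asarray(y, dtype=float)
    n = yv.size
    pool = list(pool)
    current: list[str] = []
    cur_ic = _ic(np.empty((n, 0)), yv, penalty)
    trace = [cur_ic]
    max_k = n - 2  # keep the residual df positive
    while True:
        moves: list[tuple[float, str, str]] = []
        if len(current) < max_k:
            for c in pool:
                if c not in current:
                    moves.append((
                        _ic(X[current + [c]].to_numpy(dtype=float), yv, penalty), "add", c))
        for c in current:
            rest = [d for d in current if d != c]
            moves.append((_ic(X[rest].to_numpy(dtype=float) if rest
                              else np.empty((n, 0)), yv, penalty), "drop", c))
        if not moves:
            break
        best = min(moves, key=lambda t: t[0])
        if best[0] >= cur_ic - 1e-10:
            break
        cur_ic = best[0]
        if best[1] == "add":
            current.append(best[2])
        else:
            current.remove(best[2])
        trace.append(cur_ic)
    cols = tuple(X.columns)
    mask = np.array([c in current for c in cols])
    return SelectionResult(mask=mask, column_names=cols, fitness=float(cur_ic),
                           history=tuple(trace), method=method)


def stepwise_aic(X_train: pd.DataFrame, y_train: Sequence[float]) -> SelectionResult:
    """Bidirectional stepwise selection minimizing
    ``AIC = n·ln(RSS/n) + 2·(k+1)``, starting from the intercept-only model.
    Each step applies the single addition or removal with the lowest AIC and
    stops when no move improves it."""
    return _greedy_bidirectional(X_train, y_train, penalty=2.0,
                                 pool=list(X_train.columns), method="stepwise")


def bic_refit(X_train: pd.DataFrame, y_train: Sequence[float],
              pool_mask: Sequence[bool]) -> SelectionResult:
    """Greedy bidirectional search minimizing
    ``BIC = n·ln(RSS/n) + ln(n)·(k+1)`` within a previously selected pool."""
    pool_mask = np.asarray(pool_mask, dtype=bool)
    if pool_mask.size != X_train.shape[1]:
        raise ValueError("pool_mask length must match the number of columns")
    pool = [c for c, m in zip(X_train.columns, pool_mask) if m]
    if not pool:
        raise ValueError("bic_refit: empty pool")
    n = len(X_train)
    return _greedy_bidirectional(X_train, y_train, penalty=math.log(n),
                                 pool=pool, method="BIC")
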