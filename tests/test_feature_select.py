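import itertools
import math

import numpy as np
import pandas as pd
import pytest

from qsarkit import (GAConfig, adjusted_r2, bic_refit, ga_fitness, ga_select,
                     stepwise_aic, vif_filter)
from qsarkit.feature_select import _ic


def exhaustive_best(X, y):
    """Oracle: enumerate every non-empty mask and return the best fitness."""
    p = X.shape[1]
    best_fit, best_mask = -math.inf, None
    for bits in itertools.product([False, True], repeat=p):
        mask = np.array(bits)
        if not mask.any():
            continue
        f = ga_fitness(mask, X, y)
        if f > best_fit:
            best_fit, best_mask = f, mask
    return best_fit, best_mask


class TestAdjustedR2:
    def test_formula(self):
        assert adjusted_r2(0.5, 11, 1) == pytest.approx(1 - 0.5 * 10 / 9)

    def test_perfect_fit(self):
        for n, k in [(10, 1), (50, 8), (5, 2)]:
            assert adjusted_r2(1.0, n, k) == pytest.approx(1.0)

    def test_penalty_dominates(self):
        assert adjusted_r2(0.5, 10, 8) < 0.5

    def test_undefined(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 5, 4)


class TestGAFitness:
    def test_matches_independent_ols(self, small_linear):
        from sklearn.linear_model import LinearRegression
        from sklearn.metrics import r2_score
        X, y, _ = small_linear
        mask = np.zeros(10, dtype=bool)
        mask[[1, 4, 7]] = True
        lr = LinearRegression().fit(X.loc[:, mask], y)
        r2 = r2_score(y, lr.predict(X.loc[:, mask]))
        expected = adjusted_r2(r2, len(y), 3) - 3 / len(y)
        assert ga_fitness(mask, X, y) == pytest.approx(expected, abs=1e-10)

    def test_empty_mask_sentinel(self, small_linear):
        X, y, _ = small_linear
        assert ga_fitness(np.zeros(10, dtype=bool), X, y) == -math.inf

    def test_singular_design_sentinel(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        X = pd.DataFrame({"A": x, "B": x})  # perfectly collinear
        y = x + 0.1 * rng.standard_normal(20)
        assert ga_fitness([True, True], X, y) == -math.inf

    def test_true_support_beats_supersets_noiseless(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((60, 10)),
                         columns=[f"D{i}" for i in range(10)])
        y = 2 * X["D0"] - X["D3"] + 0.5 * X["D8"]  # exact, no noise
        support = np.zeros(10, dtype=bool)
        support[[0, 3, 8]] = True
        f_support = ga_fitness(support, X, y)
        for extra in range(10):
            if support[extra]:
                continue
            superset = support.copy()
            superset[extra] = True
            assert ga_fitness(superset, X, y) < f_support


class TestGASelect:
    def test_attains_exhaustive_optimum(self, small_linear):
        X, y, _ = small_linear
        X8 = X.iloc[:, :8]
        oracle, _ = exhaustive_best(X8, y)
        res = ga_select(X8, y, GAConfig(population_size=60, max_generations=60,
                                        patience=60, seed=0))
        assert res.fitness == pytest.approx(oracle, abs=1e-10)

    def test_deterministic(self, small_linear):
        X, y, _ = small_linear
        cfg = GAConfig(seed=123)
        a = ga_select(X, y, cfg)
        b = ga_select(X, y, cfg)
        assert np.array_equal(a.mask, b.mask)
        assert a.history == b.history

    def test_history_non_decreasing(self, small_linear):
        X, y, _ = small_linear
        for seed in range(3):
            h = np.array(ga_select(X, y, GAConfig(seed=seed)).history)
            assert np.all(np.diff(h) >= 0)

    def test_pure_noise_penalty_active(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((60, 8)),
                         columns=[f"D{i}" for i in range(8)])
        sizes, fits = [], []
        for seed in range(10):
            y = rng.standard_normal(60)
            res = ga_select(X, y, GAConfig(population_size=40, max_generations=40,
                                           patience=40, seed=seed))
            oracle, _ = exhaustive_best(X, y)
            assert res.fitness <= oracle + 1e-12
            sizes.append(res.mask.sum())
            fits.append(res.fitness)
        assert np.median(sizes) <= 3  # k/n penalty keeps noise models small
        assert np.median(fits) < 0.2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(crossover_rate=1.5)


class TestVIF:
    def test_orthogonal_all_retained(self):
        X = pd.DataFrame({"A": [1.0, 1, -1, -1], "B": [1.0, -1, 1, -1]})
        res = vif_filter(X)
        assert res.selected_names == ("A", "B")
        assert res.fitness == pytest.approx(1.0)

    def test_exact_sum_reduced(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        X = pd.DataFrame({"A": a, "B": b, "C": a + b, "D": rng.standard_normal(30)})
        res = vif_filter(X, vif_max=10)
        kept = list(res.selected_names)
        # recompute all VIFs on the output and assert the bound
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        arr = X[kept].to_numpy()
        for j in range(len(kept)):
            assert variance_inflation_factor(arr, j) <= 10

    def test_single_column_identity(self):
        X = pd.DataFrame({"A": [1.0, 2, 3]})
        assert vif_filter(X).selected_names == ("A",)


class TestStepwiseAIC:
    def test_null_retained_under_independence(self):
        # With one candidate predictor AIC admits a pure-noise variable only
        # when its chi2(1) deviance drop exceeds 2 (prob ~ 0.157), so the
        # null model survives in ~84% of replicates.
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(50):
            X = pd.DataFrame({"A": rng.standard_normal(120)})
            y = rng.standard_normal(120)
            if stepwise_aic(X, y).mask.sum() == 0:
                hits += 1
        assert hits >= 40  # >= 80% of replicates

    def test_noise_models_stay_small(self):
        # more candidates admit some noise terms, but the fitted models stay
        # far from the full model
        rng = np.random.default_rng(40)
        sizes = [stepwise_aic(
            pd.DataFrame(rng.standard_normal((120, 4)), columns=list("ABCD")),
            rng.standard_normal(120)).mask.sum() for _ in range(20)]
        assert np.median(sizes) <= 1
        assert max(sizes) < 4

    def test_recovers_true_pair(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((100, 5)),
                         columns=[f"D{i}" for i in range(5)])
        y = 1.5 * X["D1"] - 1.0 * X["D3"] + 0.05 * rng.standard_normal(100)
        sel = set(stepwise_aic(X, y).selected_names)
        assert {"D1", "D3"} <= sel

    def test_final_aic_bounds(self, small_linear):
        X, y, _ = small_linear
        res = stepwise_aic(X, y)
        n = len(y)
        yv = y.to_numpy()
        aic_null = _ic(np.empty((n, 0)), yv, 2.0)
        aic_full = _ic(X.to_numpy(), yv, 2.0)
        assert res.fitness <= aic_null + 1e-9
        assert res.fitness <= aic_full + 1e-9


class TestBICRefit:
    def test_single_informative_pool(self, small_linear):
        X, y, _ = small_linear
        pool = np.zeros(10, dtype=bool)
        pool[1] = True  # D1 carries signal
        res = bic_refit(X, y, pool)
        assert res.selected_names == ("D1",)

    def test_empty_pool_error(self, small_linear):
        X, y, _ = small_linear
        with pytest.raises(ValueError):
            bic_refit(X, y, np.zeros(10, dtype=bool))

    def test_bic_no_larger_than_aic_selection(self):
        rng = np.random.default_rng(6)
        wins = 0
        for _ in range(50):
            X = pd.DataFrame(rng.standard_normal((80, 6)),
                             columns=[f"D{i}" for i in range(6)])
            y = (X["D0"] + 0.5 * X["D2"] + 0.3 * X["D4"]
                 + 0.8 * rng.standard_normal(80))
            k_aic = stepwise_aic(X, y).mask.sum()
            k_bic = bic_refit(X, y, np.ones(6, dtype=bool)).mask.sum()
            if k_bic <= k_aic:
                wins += 1
        assert wins >= 45  # ln(n) > 2 penalty selects no more in >= 90%

    def test_final_bic_below_null(self, small_linear):
        X, y, _ = small_linear
        res = bic_refit(X, y, np.ones(10, dtype=bool))
        n = len(y)
        bic_null = _ic(np.empty((n, 0)), y.to_numpy(), math.log(n))
        assert res.fitness <= bic_null + 1e-9
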