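"""Pareto front, fitness isoclines, CV bootstrap, lowess."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microhet import pareto as pt


def brute_force_front(g, l):
    n = len(g)
    dom = np.zeros(n, bool)
    for i in range(n):
        dom[i] = np.any((g >= g[i]) & (l <= l[i]) & ((g > g[i]) | (l < l[i])))
    return ~dom


class TestMinmaxNormalize:
    def test_values(self):
        np.testing.assert_allclose(pt.minmax_normalize([1, 2, 3]), [0, 0.5, 1])
        np.testing.assert_allclose(pt.minmax_normalize([0.0, 0.25, 1.0]),
                                   [0.0, 0.25, 1.0])

    def test_affine_invariance(self, rng):
        v = rng.normal(size=30)
        np.testing.assert_allclose(pt.minmax_normalize(v),
                                   pt.minmax_normalize(5.0 * v - 3.0))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pt.minmax_normalize([2.0, 2.0])


class TestFitness:
    def test_ratio(self):
        assert pt.fitness(0.8, 0.4) == pytest.approx(2.0)
        np.testing.assert_allclose(pt.fitness([0.8, 0.4], [0.4, 0.2]), [2.0, 2.0])

    def test_zero_lag_rejected(self):
        with pytest.raises(ValueError):
            pt.fitness(0.5, 0.0)

    def test_uniform_cloud_differs_from_observed_coupled_population(self, rng):
        # coupled population concentrated along one isocline vs the
        # uniform-rectangle baseline expected "by random choice"
        lag = rng.uniform(1.0, 3.0, 800)
        growth = 0.5 / lag + rng.normal(0, 0.01, 800)
        f = pt.fitness_scores(growth, lag)
        finite = np.isfinite(f)
        bins = np.linspace(0, np.quantile(f[finite], 0.98), 25)
        obs, _ = np.histogram(f[finite], bins=bins)
        exp = pt.random_fitness_baseline(growth, lag, bins=bins, seed=3)
        chi = np.sum((obs - exp) ** 2 / np.maximum(exp, 1.0))
        from scipy.stats import chi2
        assert chi2.sf(chi, df=len(bins) - 1) < 1e-3


class TestParetoFront:
    def test_strict_domination(self):
        mask = pt.pareto_front([2.0, 1.0], [1.0, 1.0])
        assert mask.tolist() == [True, False]

    def test_chain_without_domination(self):
        mask = pt.pareto_front([1, 2, 3], [1, 2, 3])
        assert mask.all()

    def test_single_point(self):
        assert pt.pareto_front([1.0], [5.0]).tolist() == [True]

    def test_duplicates_mutually_nondominated(self):
        mask = pt.pareto_front([1.0, 1.0, 0.5], [2.0, 2.0, 2.0])
        assert mask.tolist() == [True, True, False]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=1, max_value=120), st.integers(0, 2 ** 31 - 1))
    def test_matches_bruteforce_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 12, n).astype(float)  # ties likely
        l = rng.integers(0, 12, n).astype(float)
        np.testing.assert_array_equal(pt.pareto_front(g, l),
                                      brute_force_front(g, l))

    def test_every_point_on_front_or_dominated(self, rng):
        g, l = rng.normal(size=300), rng.normal(size=300)
        mask = pt.pareto_front(g, l)
        for i in np.where(~mask)[0]:
            front = np.where(mask)[0]
            assert np.any((g[front] >= g[i]) & (l[front] <= l[i])
                          & ((g[front] > g[i]) | (l[front] < l[i])))


class TestEqualFitnessModel:
    def test_values_and_limits(self):
        m = pt.FitnessModel(total_time=10.0, divisions_constant=5.0)
        assert pt.equal_fitness_lag(m, 1.0) == pytest.approx(5.0)
        assert pt.equal_fitness_lag(m, 0.5) == pytest.approx(0.0)  # lambda=c/T
        assert pt.equal_fitness_lag(m, 1e9) == pytest.approx(10.0, rel=1e-6)

    def test_infeasible_rate_rejected(self):
        m = pt.FitnessModel(10.0, 5.0)
        with pytest.raises(ValueError):
            pt.equal_fitness_lag(m, 0.4)

    def test_divisions_constant_along_curve(self):
        m = pt.FitnessModel(12.0, 4.0)
        lam = np.linspace(0.5, 5.0, 40)
        lag = pt.equal_fitness_lag(m, lam)
        np.testing.assert_allclose(lam * (m.total_time - lag), 4.0)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            pt.FitnessModel(0.0, 1.0)


class TestFitnessBandCorrelation:
    def _population(self, n=1000, couple=True, seed=0):
        rng = np.random.default_rng(seed)
        growth = rng.uniform(0.5, 2.0, n)
        lag = rng.uniform(1.0, 4.0, n)
        if couple:
            resp = 3.0 - 1.0 * growth + rng.normal(0, 0.15, n)
        else:
            resp = rng.uniform(0.5, 2.5, n)
        return pd.DataFrame({"growth_rate": growth, "lag_time": lag,
                             "resp_rate": resp})

    def test_full_band_equals_population_correlation(self):
        df = self._population()
        rho_band, _, n = pt.fitness_band_correlation(df, band=(0.0, 1.0))
        rho_all, _ = pt.spearman(df["growth_rate"], df["resp_rate"])
        assert n == len(df)
        assert rho_band == pytest.approx(rho_all)

    def test_coupled_population_negative_in_top_band(self):
        rho, p, n = pt.fitness_band_correlation(self._population(),
                                                band=(0.7, 0.8))
        assert rho < -0.5 and p < 1e-3 and n >= 10

    def test_null_population_uncorrelated(self):
        rho, p, _ = pt.fitness_band_correlation(
            self._population(couple=False), band=(0.7, 0.8))
        assert abs(rho) < 0.3

    def test_undersized_band_rejected(self):
        with pytest.raises(ValueError):
            pt.fitness_band_correlation(self._population(n=40),
                                        band=(0.70, 0.71))


class TestCVBootstrap:
    def test_constant_values_zero_cv(self):
        res = pt.cv_bootstrap(np.full(100, 5.0), n_draw=20, n_reps=50, seed=0)
        np.testing.assert_allclose(res.cvs, 0.0)

    def test_seed_reproducibility(self, rng):
        v = rng.normal(10, 2, 1000)
        a = pt.cv_bootstrap(v, n_draw=100, n_reps=200, seed=7)
        b = pt.cv_bootstrap(v, n_draw=100, n_reps=200, seed=7)
        np.testing.assert_array_equal(a.cvs, b.cvs)

    def test_nonpositive_mean_draw_flagged(self):
        v = np.concatenate([np.full(30, -1.0), np.full(5, 0.5)])
        res = pt.cv_bootstrap(v, n_draw=30, n_reps=50, seed=1)
        assert res.flagged.any()
        assert np.isnan(res.cvs[res.flagged]).all()

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError):
            pt.cv_bootstrap(np.ones(10), n_draw=20)

    def test_distribution_comparison_detects_difference(self, rng):
        a = pt.cv_bootstrap(rng.normal(10, 1, 3000), n_draw=400, n_reps=200, seed=2)
        b = pt.cv_bootstrap(rng.normal(10, 3, 3000), n_draw=400, n_reps=200, seed=2)
        _, p = pt.compare_cv_distributions(a, b)
        assert p < 1e-6


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert pt.spearman(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pt.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_independent_samples_small_rho(self, rng):
        rho, _ = pt.spearman(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rho) < 0.1

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            pt.spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pt.spearman([1, 2, 3], [1, 2, 3])


class TestLowess:
    def test_exact_on_linear_data(self, rng):
        x = np.sort(rng.uniform(0, 10, 60))
        y = 3.0 * x - 2.0
        grid, s = pt.lowess_trend(x, y, span=0.4)
        np.testing.assert_allclose(s, 3.0 * grid - 2.0, atol=1e-6)

    def test_constant_y(self, rng):
        x = np.sort(rng.uniform(0, 1, 30))
        _, s = pt.lowess_trend(x, np.full(30, 4.0), span=0.3)
        np.testing.assert_allclose(s, 4.0, atol=1e-9)

    def test_noisy_sine_smoothing(self, rng):
        x = np.sort(rng.uniform(0, 2 * np.pi, 400))
        noise_sd = 0.3
        y = np.sin(x) + rng.normal(0, noise_sd, 400)
        grid, s = pt.lowess_trend(x, y, span=0.3)
        rmse = np.sqrt(np.mean((s - np.sin(grid)) ** 2))
        assert rmse < noise_sd

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pt.lowess_trend([1, 2, 3], [1, 2, 3], span=0.5)


class TestPopulationSummary:
    def test_counts_and_cvs(self, rng):
        df = pd.DataFrame({
            "condition": ["LB"] * 300 + ["M9"] * 200,
            "growth_rate": np.concatenate([rng.normal(10, 4, 300),
                                           rng.normal(5, 0.75, 200)]),
            "lag_time": rng.normal(8, 1.2, 500),
            "resp_rate": rng.normal(2, 0.4, 500),
        })
        out = pt.colony_population_summary(df).set_index("condition")
        assert out.loc["LB", "n_colonies"] == 300
        assert out.loc["M9", "n_colonies"] == 200
        assert out.loc["LB", "cv_growth_rate"] == pytest.approx(0.4, abs=0.05)
        assert out.loc["M9", "cv_growth_rate"] == pytest.approx(0.15, abs=0.03)


def test_respired_carbon_fraction():
    assert pt.respired_carbon_fraction(2.0, 10.0) == pytest.approx(0.8)


def test_knn_mean_grid_constant_field(rng):
    x, y = rng.uniform(size=200), rng.uniform(size=200)
    _, _, grid = pt.knn_mean_grid(x, y, np.full(200, 3.0), k=10, n_grid=8)
    np.testing.assert_allclose(grid, 3.0)
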