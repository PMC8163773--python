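"""Pareto tradeoff analysis of colony phenotype populations.

Colonies are scored on two competing objectives — maximize growth rate,
minimize lag time.  The non-dominated (Pareto-optimal) subset bounds the
feasible phenotype space; fitness is approximated as the ratio of
normalized growth rate to normalized lag time, so isoclines of constant
fitness are rays in the normalized plane.  A simple exponential model of
equally fit cells (same number of divisions D within a fixed period T)
yields the inverse relation lambda * (T - T_lag) = c with c = D * ln 2,
i.e. T_lag = T - c / lambda.

Also provided: Spearman correlations of growth vs. respiration inside
fitness-quantile bands, the coefficient-of-variation bootstrap used to
compare population heterogeneity between strains, lowess trend curves,
and population summaries (counts and CVs) of colony phenotype tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitnessModel",
    "minmax_normalize",
    "fitness",
    "fitness_scores",
    "pareto_front",
    "equal_fitness_lag",
    "fitness_band_correlation",
    "random_fitness_baseline",
    "cv_bootstrap",
    "compare_cv_distributions",
    "spearman",
    "lowess_trend",
    "knn_mean_grid",
    "respired_carbon_fraction",
    "colony_population_summary",
    "CVBootstrapResult",
]


def minmax_normalize(values) -> np.ndarray:
    """Map values affinely onto [0, 1]; constant input is rejected."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        raise ValueError("cannot normalize a constant vector")
    return (v - lo) / (hi - lo)


def fitness(growth_norm, lag_norm):
    """Fitness proxy: ratio of normalized growth rate to normalized lag.

    Isoclines of constant growth/lag ratio are level sets of this score
    in the normalized phenotype plane.  Zero lag terms are rejected.
    """
    g = np.asarray(growth_norm, dtype=float)
    l = np.asarray(lag_norm, dtype=float)
    if np.any(l == 0):
        raise ValueError("zero lag term: fitness undefined")
    return g / l


def fitness_scores(growth_rate, lag_time, normalized: bool = True) -> np.ndarray:
    """Per-colony fitness over a population.

    With ``normalized=True`` (the plotted convention) both axes are
    min-max normalized first; the colony at the minimum lag then has an
    infinite score and is treated as above every finite quantile.  With
    ``normalized=False`` the raw ratio growth/lag is used.
    """
    g = np.asarray(growth_rate, dtype=float)
    l = np.asarray(lag_time, dtype=float)
    if normalized:
        g = minmax_normalize(g)
        l = minmax_normalize(l)
    with np.errstate(divide="ignore"):
        return np.where(l > 0, g / np.where(l > 0, l, 1.0), np.inf)


def pareto_front(growth_rate, lag_time) -> np.ndarray:
    """Boolean mask of the non-dominated set.

    A colony is dominated if another colony has growth rate >= and lag
    <= with strict inequality in at least one; identical points are
    mutually non-dominated.  O(n log n) sweep.
    """
    g = np.asarray(growth_rate, dtype=float)
    l = np.asarray(lag_time, dtype=float)
    n = g.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    # sort by growth desc, lag asc; sweep tracking the minimum lag among
    # points with strictly greater growth
    order = np.lexsort((l, -g))
    mask = np.zeros(n, dtype=bool)
    best_lag = np.inf  # min lag among strictly faster growers
    i = 0
    while i < n:
        j = i
        gi = g[order[i]]
        while j < n and g[order[j]] == gi:
            j += 1
        group = order[i:j]                 # equal growth, lag ascending
        group_min_lag = l[group[0]]
        for idx in group:
            # dominated by a strictly faster grower with lag <= ours, or
            # by an equal grower with strictly smaller lag
            dominated = (best_lag <= l[idx]) or (group_min_lag < l[idx])
            mask[idx] = not dominated
        best_lag = min(best_lag, group_min_lag)
        i = j
    return mask


@dataclass(frozen=True)
class FitnessModel:
    """Equal-fitness exponential model: lambda * (T - T_lag) = c.

    ``total_time`` T (h) is the fixed evaluation period and
    ``divisions_constant`` c = D * ln 2 encodes the common number of
    divisions D reached by equally fit cells.
    """

    total_time: float
    divisions_constant: float

    def __post_init__(self):
        if self.total_time <= 0 or self.divisions_constant <= 0:
            raise ValueError("total_time and divisions_constant must be > 0")


def equal_fitness_lag(model: FitnessModel, growth_rate) -> np.ndarray:
    """Lag time of an equally fit cell at growth rate lambda.

    T_lag = T - c / lambda; feasible only for lambda >= c / T (lag >= 0).
    """
    lam = np.asarray(growth_rate, dtype=float)
    lam_min = model.divisions_constant / model.total_time
    if np.any(lam < lam_min * (1 - 1e-12)):
        raise ValueError("growth rate below c/T: no feasible lag")
    return model.total_time - model.divisions_constant / lam


def fitness_band_correlation(phenotypes: pd.DataFrame,
                             band: tuple[float, float] = (0.7, 0.8),
                             normalized: bool = True):
    """Growth-respiration Spearman correlation inside a fitness band.

    Selects colonies whose fitness lies between the ``band`` quantiles
    of the population fitness distribution (linear-interpolation
    quantiles over the finite scores) and returns (rho, p, n) for
    growth_rate vs. resp_rate inside the band.
    """
    f = fitness_scores(phenotypes["growth_rate"], phenotypes["lag_time"],
                       normalized=normalized)
    finite = np.isfinite(f)
    qlo = np.quantile(f[finite], band[0])
    qhi = np.inf if band[1] >= 1.0 else np.quantile(f[finite], band[1])
    member = (f >= qlo) & (f <= qhi)
    if member.sum() < 10:
        raise ValueError(f"band {band} holds {int(member.sum())} colonies; need >= 10")
    sub = phenotypes.loc[member]
    rho, p = spearman(sub["growth_rate"], sub["resp_rate"])
    return rho, p, int(member.sum())


def random_fitness_baseline(growth_rate, lag_time, bins,
                            n_draws: int = 10_000, seed: int = 0) -> np.ndarray:
    """Expected fitness histogram under random phenotype placement.

    Draws points uniformly over the bounding rectangle of the normalized
    (growth, lag) cloud, computes their fitness and returns histogram
    counts scaled to the observed population size.
    """
    g = minmax_normalize(growth_rate)
    l = minmax_normalize(lag_time)
    rng = np.random.default_rng(seed)
    gu = rng.uniform(g.min(), g.max(), size=n_draws)
    lu = rng.uniform(max(l.min(), 1e-9), l.max(), size=n_draws)
    fu = gu / lu
    counts, _ = np.histogram(fu, bins=bins)
    return counts * (len(g) / n_draws)


@dataclass
class CVBootstrapResult:
    """CV distribution over repeated subsamples of a population."""

    cvs: np.ndarray
    n_draw: int
    n_reps: int
    flagged: np.ndarray  # draws with non-positive mean

    @property
    def mean_cv(self) -> float:
        return float(np.nanmean(self.cvs))


def cv_bootstrap(values, n_draw: int = 400, n_reps: int = 1000,
                 seed: int = 0) -> CVBootstrapResult:
    """Coefficient-of-variation bootstrap: ``n_reps`` random selections
    of ``n_draw`` colonies (without replacement within a draw), CV =
    sd/mean per draw.  Draws with non-positive mean are flagged (CV set
    to NaN)."""
    v = np.asarray(values, dtype=float)
    if n_draw > v.size:
        raise ValueError("n_draw exceeds population size")
    rng = np.random.default_rng(seed)
    cvs = np.empty(n_reps)
    flagged = np.zeros(n_reps, dtype=bool)
    for r in range(n_reps):
        draw = v[rng.choice(v.size, size=n_draw, replace=False)]
        m = draw.mean()
        if m <= 0:
            flagged[r] = True
            cvs[r] = np.nan
        else:
            cvs[r] = draw.std(ddof=1) / m
    return CVBootstrapResult(cvs=cvs, n_draw=n_draw, n_reps=n_reps, flagged=flagged)


def compare_cv_distributions(a: CVBootstrapResult, b: CVBootstrapResult):
    """Two-sided t-test between two bootstrap CV distributions."""
    res = stats.ttest_ind(a.cvs[~a.flagged], b.cvs[~b.flagged])
    return float(res.statistic), float(res.pvalue)


def spearman(x, y):
    """Spearman rank correlation (midrank ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def lowess_trend(x, y, span: float = 0.3, grid=None, n_grid: int = 100):
    """Locally weighted (tricube) linear regression on a grid.

    At each grid point the ceil(span * n) nearest observations receive
    tricube weights over the local bandwidth and a weighted linear fit
    is evaluated there.  Returns (grid, smoothed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    k = max(int(np.ceil(span * n)), 2)
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        xw, yw = x[idx], y[idx]
        sw = w.sum()
        xb = (w * xw).sum() / sw
        yb = (w * yw).sum() / sw
        sxx = (w * (xw - xb) ** 2).sum()
        slope = (w * (xw - xb) * (yw - yb)).sum() / sxx if sxx > 0 else 0.0
        out[i] = yb + slope * (g - xb)
    return grid, out


def knn_mean_grid(x, y, z, k: int = 25, n_grid: int = 50):
    """k-NN mean of ``z`` on a regular (x, y) grid (heatmap helper)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    gx = np.linspace(x.min(), x.max(), n_grid)
    gy = np.linspace(y.min(), y.max(), n_grid)
    k = min(k, x.size)
    out = np.empty((n_grid, n_grid))
    for i, yi in enumerate(gy):
        d2 = (x[None, :] - gx[:, None]) ** 2 + (y[None, :] - yi) ** 2
        idx = np.argpartition(d2, k - 1, axis=1)[:, :k]
        out[i] = z[idx].mean(axis=1)
    return gx, gy, out


def respired_carbon_fraction(acetate_flux, glucose_flux):
    """Fraction of glucose carbon not secreted as acetate:
    1 - acetate_carbon_flux / glucose_carbon_flux."""
    return 1.0 - np.asarray(acetate_flux, dtype=float) / np.asarray(glucose_flux, dtype=float)


def colony_population_summary(phenotypes: pd.DataFrame,
                              group_cols=("condition",),
                              value_cols=("growth_rate", "lag_time", "resp_rate")
                              ) -> pd.DataFrame:
    """Colony counts and per-parameter CVs by condition/plate group.

    Intended for recomputing population-level summaries (colony counts,
    growth-parameter CVs) from a deposited colony-phenotype table.
    """
    group_cols = [c for c in group_cols if c in phenotypes.columns]
    rows = []
    grouped = phenotypes.groupby(list(group_cols)) if group_cols else [((), phenotypes)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(group_cols, key))
        rec["n_colonies"] = len(sub)
        for c in value_cols:
            v = sub[c].to_numpy(float)
            v = v[np.isfinite(v)]
            rec[f"cv_{c}"] = v.std(ddof=1) / v.mean() if v.size > 1 and v.mean() != 0 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
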