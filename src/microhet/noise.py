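"""Gene-expression noise decomposition and enrichment statistics.

Expression noise of a protein p is the squared coefficient of variation
across single cells, eta_p = sigma_p^2 / mu_p^2.  Because noise scales
inversely with mean abundance, a protein's noise is only interpretable
against proteins of similar abundance: the expected noise eta_bar_p is
the running mean of eta over the 5% of proteins nearest in log10
abundance, and the deviating noise eps_p = eta_p / eta_bar_p measures
excess variability beyond the abundance-noise scaling law (eps = 1, or
log2 eps = 0, means exactly as noisy as expected).

Set-level statistics (gene ontology terms, TF regulons) are scored by a
permutation test: the observed set statistic (mean or median score of
members) against same-size random draws, with the add-one correction
p = (1 + #{null >= obs}) / (1 + n_permutations), and Storey q-values
for multiple-testing control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "compute_noise",
    "smooth_mean_noise",
    "deviating_noise",
    "NoiseModel",
    "NoiseResults",
    "set_enrichment",
    "tf_enrichment",
    "protein_flux_scaling",
    "storey_qvalues",
]


def compute_noise(mu, sigma):
    """Expression noise eta = sigma^2 / mu^2 (squared CV)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    return sigma ** 2 / mu ** 2


def smooth_mean_noise(mu, eta, neighbor_fraction: float = 0.05):
    """Expected noise: mean eta over the nearest proteins in log10(mu).

    For each protein the window holds the ceil(neighbor_fraction * N)
    proteins (the protein itself included) closest in log10 abundance;
    eta_bar is their plain average.
    """
    mu = np.asarray(mu, dtype=float)
    eta = np.asarray(eta, dtype=float)
    n = mu.size
    if n < 20:
        raise ValueError("need at least 20 records to smooth")
    if not 0 < neighbor_fraction <= 1:
        raise ValueError("neighbor_fraction must be in (0, 1]")
    k = int(np.ceil(neighbor_fraction * n))
    lm = np.log10(mu)
    # pairwise distances in manageable chunks; k-NN mean per row
    eta_bar = np.empty(n)
    chunk = max(1, int(2e7) // n)
    for start in range(0, n, chunk):
        d = np.abs(lm[start:start + chunk, None] - lm[None, :])
        idx = np.argpartition(d, k - 1, axis=1)[:, :k]
        eta_bar[start:start + chunk] = eta[idx].mean(axis=1)
    return eta_bar


def deviating_noise(eta, eta_bar):
    """Deviating noise eps = eta / eta_bar."""
    eta = np.asarray(eta, dtype=float)
    eta_bar = np.asarray(eta_bar, dtype=float)
    if np.any(eta_bar <= 0):
        raise ValueError("eta_bar must be > 0")
    return eta / eta_bar


class NoiseResults:
    """Deviating-noise estimates for a protein table.

    ``records`` holds protein_id, mu, sigma, eta, eta_bar, epsilon and
    log2_epsilon; enrichment methods run the permutation machinery on
    the epsilon scores.
    """

    def __init__(self, model: "NoiseModel", records: pd.DataFrame):
        self.model = model
        self.records = records

    @property
    def epsilon(self) -> pd.Series:
        return self.records.set_index("protein_id")["epsilon"]

    def set_enrichment(self, sets, n_permutations: int = 2000, seed: int = 0,
                       statistic: str = "mean", scores=None) -> pd.DataFrame:
        scores = self.epsilon if scores is None else scores
        return set_enrichment(scores, sets, n_permutations=n_permutations,
                              seed=seed, statistic=statistic)

    def tf_enrichment(self, tf_targets, n_permutations: int = 2000,
                      seed: int = 0) -> pd.DataFrame:
        return tf_enrichment(self.epsilon, tf_targets,
                             n_permutations=n_permutations, seed=seed)

    def summary(self) -> str:
        r = self.records
        top = r.nlargest(5, "epsilon")[["protein_id", "mu", "epsilon"]]
        lines = [
            "Deviating-noise estimation",
            "=" * 40,
            f"proteins:            {len(r)}",
            f"neighbor fraction:   {self.model.neighbor_fraction}",
            f"median eta:          {r['eta'].median():.4g}",
            f"median epsilon:      {r['epsilon'].median():.4g}",
            "top deviating proteins:",
        ]
        lines += [f"  {t.protein_id}  mu={t.mu:.4g}  eps={t.epsilon:.3f}"
                  for t in top.itertuples()]
        return "\n".join(lines)


class NoiseModel:
    """Deviating-noise model over a protein summary table.

    Parameters
    ----------
    table : DataFrame with columns protein_id, mu, sigma (and optional
        essential flag).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"protein_id", "mu", "sigma"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.neighbor_fraction = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, protein_id="protein_id",
                       mu="mu", sigma="sigma") -> "NoiseModel":
        return cls(df.rename(columns={protein_id: "protein_id",
                                      mu: "mu", sigma: "sigma"}))

    def fit(self, neighbor_fraction: float = 0.05) -> NoiseResults:
        self.neighbor_fraction = neighbor_fraction
        mu = self.table["mu"].to_numpy(float)
        sigma = self.table["sigma"].to_numpy(float)
        eta = compute_noise(mu, sigma)
        eta_bar = smooth_mean_noise(mu, eta, neighbor_fraction)
        eps = deviating_noise(eta, eta_bar)
        records = self.table.copy()
        records["eta"] = eta
        records["eta_bar"] = eta_bar
        records["epsilon"] = eps
        records["log2_epsilon"] = np.log2(eps)
        return NoiseResults(self, records)


# ---------------------------------------------------------------------------
# permutation set enrichment
# ---------------------------------------------------------------------------

_STATS = {"mean": np.mean, "median": np.median}


def set_enrichment(scores, sets: dict, n_permutations: int = 2000,
                   seed: int = 0, statistic: str = "mean") -> pd.DataFrame:
    """Permutation enrichment of per-protein scores in named sets.

    For each set the observed statistic (mean or median member score)
    is compared to ``n_permutations`` same-size random draws from all
    scored proteins.  Two one-sided add-one p-values are returned
    (p_high: enrichment for high scores; p_low: depletion), each with
    Storey q-values across sets.  Members absent from ``scores`` are
    dropped with a logged count; empty sets are skipped with a warning.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if statistic not in _STATS:
        raise ValueError("statistic must be 'mean' or 'median'")
    scores = pd.Series(scores).astype(float)
    vals = scores.to_numpy()
    index = pd.Index(scores.index)
    n = vals.size
    rng = np.random.default_rng(seed)
    stat_fn = _STATS[statistic]

    rows = []
    for name, members in sets.items():
        members = list(members)
        pos = index.get_indexer(pd.Index(members).unique())
        unknown = int((pos < 0).sum())
        if unknown:
            logger.info("set %s: %d unknown ids ignored", name, unknown)
        pos = pos[pos >= 0]
        if pos.size == 0:
            logger.warning("set %s has no scored members; skipped", name)
            continue
        obs = float(stat_fn(vals[pos]))
        # independent without-replacement null draws per set (sharing
        # one draw matrix across sets correlates their p-values)
        keys = rng.random((n_permutations, n))
        idx = np.argpartition(keys, pos.size - 1, axis=1)[:, :pos.size]
        null = stat_fn(vals[idx], axis=1)
        # tolerance so exact ties (e.g. the all-members set) are not
        # broken by floating-point summation order
        eps = 1e-9 * max(1.0, abs(obs))
        p_high = (1.0 + np.sum(null >= obs - eps)) / (1.0 + n_permutations)
        p_low = (1.0 + np.sum(null <= obs + eps)) / (1.0 + n_permutations)
        rows.append((name, pos.size, obs, p_high, p_low))
    out = pd.DataFrame(rows, columns=["set", "n", "statistic", "p_high", "p_low"])
    if len(out):
        out["q_high"] = storey_qvalues(out["p_high"].to_numpy())
        out["q_low"] = storey_qvalues(out["p_low"].to_numpy())
    return out


def tf_enrichment(epsilon, tf_targets: dict, n_permutations: int = 2000,
                  seed: int = 0, bonferroni_alpha: float = 1e-4) -> pd.DataFrame:
    """TF-regulon enrichment for high deviating noise.

    Uses the median target epsilon as the set statistic.  Alongside the
    permutation p-value, reports the Bonferroni-corrected significance
    threshold bonferroni_alpha / n_TFs used to call significant TFs.
    """
    res = set_enrichment(epsilon, tf_targets, n_permutations=n_permutations,
                         seed=seed, statistic="median")
    res = res.rename(columns={"set": "tf", "statistic": "median_epsilon",
                              "n": "n_targets"})
    if len(res):
        res["bonferroni_threshold"] = bonferroni_alpha / len(res)
        res["significant"] = res["p_high"] <= res["bonferroni_threshold"]
    return res


def protein_flux_scaling(protein: pd.DataFrame, flux: pd.DataFrame,
                         mapping=None) -> pd.DataFrame:
    """OLS proportionality between enzyme abundance and reaction flux.

    For each mapped (enzyme, reaction) pair, ordinary least squares of
    flux on protein copy number across the shared conditions; returns
    slope, two-sided slope p-value, R^2 and the condition count.
    ``mapping`` defaults to identity over shared row labels; pairs with
    fewer than 3 shared conditions are rejected.
    """
    if mapping is None:
        shared = protein.index.intersection(flux.index)
        skipped = len(protein.index) - len(shared)
        if skipped:
            logger.info("%d enzymes without a mapped reaction skipped", skipped)
        mapping = [(e, e) for e in shared]
    rows = []
    for enzyme, reaction in mapping:
        if enzyme not in protein.index or reaction not in flux.index:
            logger.info("unmapped pair (%s, %s) skipped", enzyme, reaction)
            continue
        x = protein.loc[enzyme]
        y = flux.loc[reaction]
        cond = x.index.intersection(y.index)
        if len(cond) < 3:
            raise ValueError(
                f"pair ({enzyme}, {reaction}) has {len(cond)} shared conditions; need >= 3")
        lr = stats.linregress(x[cond].to_numpy(float), y[cond].to_numpy(float))
        rows.append((enzyme, reaction, lr.slope, lr.pvalue,
                     lr.rvalue ** 2, len(cond)))
    return pd.DataFrame(rows, columns=["enzyme_id", "reaction_id", "slope",
                                       "p_value", "r_squared", "n_conditions"])


def storey_qvalues(p_values, lambdas=None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    grid lambda = 0.05, 0.10, ..., 0.95, a cubic smoother is fitted and
    evaluated at the largest lambda, and the estimate clipped to (0, 1].
    q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if m < 100:
        pi0 = 1.0  # too few tests to estimate pi0 stably
    else:
        coef = np.polyfit(lambdas, pi0_grid, deg=3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
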