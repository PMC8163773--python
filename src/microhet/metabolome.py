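"""Untargeted metabolome statistics: annotation, differential abundance,
pathway enrichment, starvation time courses.

Ions from flow-injection mass spectrometry are putatively annotated by
matching the measured m/z against expected adduct masses of a supplied
metabolite list within a ppm tolerance (deprotonated [M-H]- by default,
the usual negative-mode assumption); ambiguous multi-metabolite matches
are retained and flagged.  Differential abundance between two sample
groups uses a Welch two-tailed t-test on log2(intensity + 1) with Storey
q-values; pathway enrichment reuses the permutation machinery of the
noise module with |log2 fold change| as the metabolite score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .noise import set_enrichment, storey_qvalues

logger = logging.getLogger(__name__)

__all__ = [
    "PROTON_MASS",
    "DEFAULT_ADDUCTS",
    "annotate_ions",
    "collapse_ions_to_metabolites",
    "differential_abundance",
    "pathway_enrichment",
    "starvation_timecourse_summary",
]

PROTON_MASS = 1.007276
DEFAULT_ADDUCTS = {"[M-H]-": -PROTON_MASS}


def annotate_ions(ion_mz, metabolite_masses, tolerance_ppm: float = 10.0,
                  adducts: dict[str, float] | None = None) -> pd.DataFrame:
    """Match ion m/z values to metabolites by molar mass.

    ``ion_mz``: Series of m/z indexed by ion id.  ``metabolite_masses``:
    Series of neutral monoisotopic masses indexed by metabolite id.  For
    each adduct the expected ion mass is neutral mass + adduct shift;
    every metabolite within ``tolerance_ppm`` matches.  Ions matching
    more than one metabolite are flagged ambiguous.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    adducts = DEFAULT_ADDUCTS if adducts is None else adducts
    ion_mz = pd.Series(ion_mz).astype(float)
    masses = pd.Series(metabolite_masses).astype(float)

    rows = []
    for adduct, shift in adducts.items():
        expected = (masses + shift).to_numpy()
        order = np.argsort(expected)
        exp_sorted = expected[order]
        ids_sorted = masses.index.to_numpy()[order]
        for ion, mz in ion_mz.items():
            tol = mz * tolerance_ppm * 1e-6
            lo = np.searchsorted(exp_sorted, mz - tol, side="left")
            hi = np.searchsorted(exp_sorted, mz + tol, side="right")
            for j in range(lo, hi):
                ppm = (mz - exp_sorted[j]) / exp_sorted[j] * 1e6
                rows.append((ion, ids_sorted[j], adduct, ppm))
    out = pd.DataFrame(rows, columns=["ion_id", "metabolite_id", "adduct", "ppm_error"])
    if len(out):
        counts = out.groupby("ion_id")["metabolite_id"].transform("nunique")
        out["ambiguous"] = counts > 1
    else:
        out["ambiguous"] = pd.Series(dtype=bool)
    return out


def collapse_ions_to_metabolites(intensities: pd.DataFrame,
                                 annotations: pd.DataFrame) -> pd.DataFrame:
    """One intensity row per metabolite: for metabolites matched by
    several ions, the ion with the highest median intensity represents
    the metabolite."""
    med = intensities.median(axis=1)
    picks = {}
    for met, sub in annotations.groupby("metabolite_id"):
        ions = [i for i in sub["ion_id"].unique() if i in intensities.index]
        if not ions:
            continue
        picks[met] = max(ions, key=lambda i: med.loc[i])
    out = intensities.loc[list(picks.values())].copy()
    out.index = pd.Index(list(picks.keys()), name="metabolite_id")
    return out


def differential_abundance(intensities: pd.DataFrame, sample_groups: dict,
                           group_a: str, group_b: str) -> pd.DataFrame:
    """Differential abundance of group_a vs. group_b.

    ``intensities``: metabolites x samples (raw scale).  Per metabolite:
    log2 fold change of group means (log2((mean_a+1)/(mean_b+1))),
    Welch two-tailed t-test on log2(intensity+1), Storey q-values over
    all metabolites.  Zero-variance cases are flagged ``degenerate``
    with p = 1.
    """
    cols_a = [s for s, g in sample_groups.items() if g == group_a and s in intensities.columns]
    cols_b = [s for s, g in sample_groups.items() if g == group_b and s in intensities.columns]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    a = intensities[cols_a].to_numpy(float)
    b = intensities[cols_b].to_numpy(float)
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2_fc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(tt.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d metabolites with degenerate variance flagged", degenerate.sum())
        p = np.where(degenerate, 1.0, p)
    q = storey_qvalues(p)
    return pd.DataFrame({
        "metabolite_id": intensities.index,
        "log2_fold_change": log2_fc,
        "p_value": p,
        "q_value": q,
        f"mean_{group_a}": mean_a,
        f"mean_{group_b}": mean_b,
        "degenerate": degenerate,
    }).set_index("metabolite_id")


def pathway_enrichment(diff: pd.DataFrame, pathways: dict,
                       n_permutations: int = 2000, seed: int = 0,
                       signed: bool = False) -> pd.DataFrame:
    """Permutation pathway enrichment on differential-abundance scores.

    Scores are |log2 fold change| (or the signed change with
    ``signed=True``); delegates to the permutation set-enrichment with
    the mean as set statistic and Storey q-values across pathways.
    """
    scores = diff["log2_fold_change"]
    if not signed:
        scores = scores.abs()
    res = set_enrichment(scores, pathways, n_permutations=n_permutations,
                         seed=seed, statistic="mean")
    return res.rename(columns={"set": "pathway"})


def starvation_timecourse_summary(intensities: pd.DataFrame,
                                  sample_sheet: pd.DataFrame,
                                  timepoints=None):
    """Per-metabolite mean +/- sd trajectories per strain.

    ``sample_sheet`` columns: sample, strain, timepoint (replicates are
    the remaining rows per cell).  Returns (trajectories, diffs):
    trajectories long-form (metabolite_id, strain, timepoint, mean, sd,
    n); diffs a per-timepoint differential-abundance table between the
    two strains (when exactly two strains are present and both have >= 2
    replicates at that timepoint).
    """
    sheet = sample_sheet.set_index("sample")
    samples = [s for s in intensities.columns if s in sheet.index]
    sheet = sheet.loc[samples]
    if timepoints is None:
        timepoints = sorted(sheet["timepoint"].unique())
    strains = list(pd.unique(sheet["strain"]))

    rows = []
    for strain in strains:
        for tp in timepoints:
            cols = sheet.index[(sheet["strain"] == strain)
                               & (sheet["timepoint"] == tp)].tolist()
            if not cols:
                logger.warning("no samples for strain=%s timepoint=%s; skipped",
                               strain, tp)
                continue
            sub = intensities[cols]
            block = pd.DataFrame({
                "metabolite_id": intensities.index,
                "strain": strain,
                "timepoint": tp,
                "mean": sub.mean(axis=1).to_numpy(),
                "sd": sub.std(axis=1, ddof=1).to_numpy() if len(cols) > 1 else 0.0,
                "n": len(cols),
            })
            rows.append(block)
    traj = pd.concat(rows, ignore_index=True)

    diffs = []
    if len(strains) == 2:
        s1, s2 = strains
        for tp in timepoints:
            groups = {s: f"{sheet.loc[s, 'strain']}"
                      for s in sheet.index[sheet["timepoint"] == tp]}
            n1 = sum(1 for g in groups.values() if g == s1)
            n2 = sum(1 for g in groups.values() if g == s2)
            if n1 < 2 or n2 < 2:
                logger.warning("timepoint %s lacks replicates; diff skipped", tp)
                continue
            d = differential_abundance(intensities[list(groups)], groups, s1, s2)
            d = d.reset_index()
            d.insert(1, "timepoint", tp)
            diffs.append(d)
    diffs = pd.concat(diffs, ignore_index=True) if diffs else pd.DataFrame()
    return traj, diffs
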