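"""Convenience glue from colony traces to phenotype tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .growth import GompertzModel, RespirationModel

__all__ = ["fit_colony_phenotypes"]


def fit_colony_phenotypes(traces: pd.DataFrame, n_starts: int = 50,
                          min_window: int = 10,
                          lag_baseline="a_min") -> pd.DataFrame:
    """Fit Gompertz growth and max-slope respiration per colony.

    ``traces``: long-form table with columns colony_id, time_h, area and
    (optionally) red, dist_center_px.  Returns one row per colony:
    colony_id, mu_max, lag_h, k, t_m, resp_rate, rss, converged
    (plus dist_center when available).
    """
    rows = []
    for cid, sub in traces.groupby("colony_id"):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(float)
        res = GompertzModel(t, sub["area"].to_numpy(float)).fit(n_starts=n_starts)
        rec = {"colony_id": cid, "converged": res.converged, "rss": res.rss}
        if res.converged:
            rec.update(mu_max=res.mu_max, lag_h=res.lag_time(baseline=lag_baseline),
                       k=res.fit.k, t_m=res.fit.t_m)
        else:
            rec.update(mu_max=np.nan, lag_h=np.nan, k=np.nan, t_m=np.nan)
        if "red" in sub.columns and sub["red"].notna().sum() >= min_window:
            ok = sub["red"].notna().to_numpy()
            r = RespirationModel(t[ok], sub.loc[ok, "red"].to_numpy(float)).fit(
                min_window=min_window)
            rec["resp_rate"] = r.alpha
        else:
            rec["resp_rate"] = np.nan
        if "dist_center_px" in sub.columns:
            rec["dist_center"] = float(sub["dist_center_px"].iloc[-1])
        rows.append(rec)
    return pd.DataFrame(rows)
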