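"""Colony and batch-culture growth kinetics.

Colony expansion on solid medium is modelled with the Gompertz law

    f(t) = A_min + A_delta * exp(-exp(k * (t_m - t)))

where ``A_min`` is the initial (offset) area, ``A_delta = A_max - A_min``
the total area gained, ``k`` (1/h) the maximum relative growth rate and
``t_m`` (h) the inflection time.  Closed forms follow for the maximum
absolute growth rate, f'(t_m) = A_delta * k / e, and for the lag time as
the intersection of the tangent at the inflection point with a baseline
area level.

Respiratory rate is estimated from the colony's mean red-channel
intensity trace: the steepest linear segment (alpha, in intensity
units/h) over all contiguous windows of at least ``min_window`` points.

Batch-culture (OD600) kinetics use the classical sliding-window
log-linear fit: the window of at least 100 min with the largest
exponential rate, with lag time from the intersection of the fitted
exponential with the inoculum OD.

All times are in hours internally; convert minutes at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GompertzFit",
    "GompertzModel",
    "GompertzResults",
    "RespirationModel",
    "RespirationResults",
    "BatchGrowthModel",
    "BatchGrowthEstimate",
    "gompertz_value",
    "max_growth_rate",
    "lag_time",
    "fit_gompertz",
    "respiratory_rate",
    "batch_growth_params",
]

_E = math.e


@dataclass
class GompertzFit:
    """Parameters of a fitted (or ground-truth) Gompertz curve.

    Attributes
    ----------
    a_min : float
        Baseline area (area units).
    a_delta : float
        Total area gain, ``A_max - A_min`` (> 0).
    k : float
        Maximum relative growth rate (1/h, > 0).
    t_m : float
        Inflection time (h).
    rss : float
        Residual sum of squares of the fit (0 for exact parameters).
    converged : bool
        False when no optimisation start point converged.
    """

    a_min: float
    a_delta: float
    k: float
    t_m: float
    rss: float = 0.0
    converged: bool = True


def gompertz_value(fit: GompertzFit, t):
    """Evaluate the Gompertz curve at time(s) ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    return fit.a_min + fit.a_delta * np.exp(-np.exp(fit.k * (fit.t_m - t)))


def max_growth_rate(fit: GompertzFit) -> float:
    """Maximum absolute growth rate f'(t_m) = A_delta * k / e (area/h)."""
    return fit.a_delta * fit.k / _E


def lag_time(fit: GompertzFit, baseline="a_min", convention: str = "tangent") -> float:
    """Lag time from the tangent at the inflection point.

    The tangent to f at t_m has slope A_delta*k/e and passes through
    (t_m, A_min + A_delta/e); its intersection with the area level
    ``baseline`` is

        t = t_m + (baseline - A_min - A_delta/e) * e / (A_delta * k)

    For ``baseline="a_min"`` (default) this reduces to ``t_m - 1/k``,
    the standard tangent construction.  ``baseline=0`` treats the colony
    as having zero size at inoculation, giving
    ``t_m - 1/k - A_min*e/(A_delta*k)``.

    ``convention="printed"`` returns the alternative closed form
    ``(A_min + (A_delta/e)(1 - k*t_m)) / ((A_delta/e)*k)``, which equals
    the negative of the zero-baseline tangent intersection; it is kept
    for comparison with that sign convention but the tangent
    intersection, which grows with t_m, is the default.
    """
    if fit.k <= 0:
        raise ValueError("lag_time requires k > 0")
    if fit.a_delta <= 0:
        raise ValueError("lag_time requires a_delta > 0")
    s = fit.a_delta / _E  # tangent slope is s*k
    if convention == "printed":
        return (fit.a_min + s * (1.0 - fit.k * fit.t_m)) / (s * fit.k)
    if convention != "tangent":
        raise ValueError(f"unknown lag convention {convention!r}")
    b = fit.a_min if (isinstance(baseline, str) and baseline == "a_min") else float(baseline)
    return fit.t_m + (b - fit.a_min - s) / (s * fit.k)


def _gompertz_residuals(theta, t, y):
    a_min, a_delta, k, t_m = theta
    # exp(exp(...)) overflows fast; clip the inner exponent
    inner = np.clip(k * (t_m - t), -700.0, 700.0)
    return a_min + a_delta * np.exp(-np.exp(inner)) - y


def _start_points(t, y, n_starts):
    """Deterministic data-driven multistart grid.

    A_min from the first observed area, A_delta from the observed range,
    t_m spanning the observed window, k log-spaced around the scale set
    by the dynamic range over the duration.
    """
    t0, t1 = float(t[0]), float(t[-1])
    span = max(t1 - t0, 1e-6)
    rng_y = float(np.ptp(y))
    a_min0 = max(float(y[0]), 1e-9)
    a_delta0 = max(rng_y, 1e-9)
    k_scale = max(4.0 / span, 1e-6)
    n_tm = max(int(round(math.sqrt(2.0 * n_starts))), 2)
    n_k = max(n_starts // n_tm, 1)
    tm_grid = np.linspace(t0, t1, n_tm)
    k_grid = k_scale * np.geomspace(0.1, 10.0, n_k)
    starts = [
        (a_min0, a_delta0, k0, tm0) for tm0 in tm_grid for k0 in k_grid
    ]
    return starts[:n_starts] if len(starts) >= n_starts else starts


def fit_gompertz(time, area, n_starts: int = 50) -> GompertzFit:
    """Fit the Gompertz law by multistart trust-region least squares.

    Parameters
    ----------
    time, area : array-like
        Strictly increasing times (h) and colony areas; >= 5 points.
    n_starts : int
        Number of deterministic start points (default 50).

    Returns
    -------
    GompertzFit with ``converged=False`` when no start converged or the
    series is degenerate (constant).
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(area, dtype=float)
    if t.ndim != 1 or t.size < 5:
        raise ValueError("fit_gompertz needs at least 5 time points")
    if y.shape != t.shape:
        raise ValueError("time and area must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(y) < 1e-12 * max(1.0, abs(float(y[0]))):
        return GompertzFit(float(y[0]), np.nan, np.nan, np.nan,
                           rss=np.nan, converged=False)

    span = float(t[-1] - t[0])
    lower = [0.0, 1e-12, 1e-12, t[0] - 2.0 * span]
    upper = [np.inf, np.inf, np.inf, t[-1] + 2.0 * span]

    best = None
    for x0 in _start_points(t, y, n_starts):
        x0 = np.clip(x0, lower, upper)
        try:
            sol = least_squares(
                _gompertz_residuals, x0, args=(t, y),
                bounds=(lower, upper), method="trf", max_nfev=400,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        rss = float(np.sum(sol.fun ** 2))
        if sol.success and np.isfinite(rss) and (best is None or rss < best[0]):
            best = (rss, sol.x)
    if best is None:
        return GompertzFit(np.nan, np.nan, np.nan, np.nan,
                           rss=np.nan, converged=False)
    rss, (a_min, a_delta, k, t_m) = best
    return GompertzFit(float(a_min), float(a_delta), float(k), float(t_m),
                       rss=rss, converged=True)


class GompertzResults:
    """Results of a Gompertz fit: parameters plus derived kinetics."""

    def __init__(self, model: "GompertzModel", fit: GompertzFit):
        self.model = model
        self.fit = fit
        self.params = {"a_min": fit.a_min, "a_delta": fit.a_delta,
                       "k": fit.k, "t_m": fit.t_m}
        self.rss = fit.rss
        self.converged = fit.converged
        self.nobs = model.time.size

    @property
    def mu_max(self) -> float:
        return max_growth_rate(self.fit)

    def lag_time(self, baseline="a_min", convention: str = "tangent") -> float:
        return lag_time(self.fit, baseline=baseline, convention=convention)

    def predict(self, t=None):
        t = self.model.time if t is None else t
        return gompertz_value(self.fit, t)

    @property
    def resid(self):
        return self.model.area - self.predict()

    def summary(self) -> str:
        lines = [
            "Gompertz colony growth fit",
            "=" * 38,
            f"nobs:        {self.nobs}",
            f"converged:   {self.converged}",
            f"A_min:       {self.fit.a_min:.6g}",
            f"A_delta:     {self.fit.a_delta:.6g}",
            f"k (1/h):     {self.fit.k:.6g}",
            f"t_m (h):     {self.fit.t_m:.6g}",
            f"rss:         {self.rss:.6g}",
        ]
        if self.converged:
            lines += [
                f"mu_max (area/h): {self.mu_max:.6g}",
                f"lag (h, tangent at A_min): {self.lag_time():.6g}",
            ]
        return "\n".join(lines)


class GompertzModel:
    """Gompertz growth model for one colony's (time, area) series.

    Examples
    --------
    >>> res = GompertzModel(time_h, area_px2).fit()
    >>> res.mu_max, res.lag_time()
    """

    def __init__(self, time, area, time_unit: str = "h"):
        t = np.asarray(time, dtype=float)
        if time_unit == "min":
            t = t / 60.0
        elif time_unit != "h":
            raise ValueError("time_unit must be 'h' or 'min'")
        self.time = t
        self.area = np.asarray(area, dtype=float)

    def fit(self, n_starts: int = 50) -> GompertzResults:
        return GompertzResults(self, fit_gompertz(self.time, self.area, n_starts))


# ---------------------------------------------------------------------------
# respiratory rate (max-slope window on the red-intensity trace)
# ---------------------------------------------------------------------------

def _window_slopes(t, y, min_window):
    """Yield (slope, intercept, i, j) for all contiguous windows y[i:j]
    of length >= min_window, via prefix sums (O(n^2) windows, O(1) each)."""
    n = t.size
    ct = np.concatenate(([0.0], np.cumsum(t)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    ctt = np.concatenate(([0.0], np.cumsum(t * t)))
    cty = np.concatenate(([0.0], np.cumsum(t * y)))
    for i in range(0, n - min_window + 1):
        m = np.arange(i + min_window, n + 1)  # window end (exclusive)
        w = (m - i).astype(float)
        st = ct[m] - ct[i]
        sy = cy[m] - cy[i]
        stt = ctt[m] - ctt[i]
        sty = cty[m] - cty[i]
        denom = w * stt - st * st
        slope = np.where(denom > 0, (w * sty - st * sy) / np.where(denom > 0, denom, 1.0), 0.0)
        intercept = (sy - slope * st) / w
        yield i, m, slope, intercept


def respiratory_rate(time, intensity, min_window: int = 10):
    """Maximum-slope linear segment of the red-intensity trace.

    Fits intensity = alpha*t + beta by OLS over every contiguous window
    of at least ``min_window`` points and returns the window with the
    largest alpha (ties: earliest start, then shortest window).

    Returns
    -------
    (alpha, beta, (start, stop)) with ``stop`` exclusive.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and intensity must be 1-D of equal length")
    if t.size < min_window:
        raise ValueError(f"need at least {min_window} points")
    best = None  # (alpha, start, stop, beta)
    for i, m, slope, intercept in _window_slopes(t, y, min_window):
        j = int(np.argmax(slope))
        a = float(slope[j])
        if best is None or a > best[0] + 1e-15:
            best = (a, i, int(m[j]), float(intercept[j]))
    alpha, start, stop, beta = best
    return alpha, beta, (start, stop)


class RespirationResults:
    """Max-slope respiratory-rate estimate for one colony."""

    def __init__(self, model, alpha, beta, window):
        self.model = model
        self.alpha = alpha      # AU/h
        self.beta = beta        # AU
        self.window = window    # (start, stop) indices, stop exclusive

    def summary(self) -> str:
        i, j = self.window
        return (
            "Respiratory-rate estimate (max-slope window)\n"
            + "=" * 44 + "\n"
            + f"alpha (AU/h): {self.alpha:.6g}\n"
            + f"beta (AU):    {self.beta:.6g}\n"
            + f"window:       points [{i}, {j}) "
            + f"({self.model.time[i]:.2f}-{self.model.time[j-1]:.2f} h)"
        )


class RespirationModel:
    """Linear max-slope model for a colony's red-intensity time series."""

    def __init__(self, time, intensity, time_unit: str = "h"):
        t = np.asarray(time, dtype=float)
        if time_unit == "min":
            t = t / 60.0
        self.time = t
        self.intensity = np.asarray(intensity, dtype=float)

    def fit(self, min_window: int = 10) -> RespirationResults:
        alpha, beta, window = respiratory_rate(self.time, self.intensity, min_window)
        return RespirationResults(self, alpha, beta, window)


# ---------------------------------------------------------------------------
# batch-culture OD600 kinetics
# ---------------------------------------------------------------------------

@dataclass
class BatchGrowthEstimate:
    """Sliding-window exponential fit of an OD600 curve.

    rate is 1/h; lag in h; window the (t_start, t_end) of the selected
    max-rate window; r_squared of the log-linear fit inside it.
    """

    rate: float
    lag: float
    window: tuple = field(default=(np.nan, np.nan))
    r_squared: float = np.nan


def batch_growth_params(time, od, min_window: float = 100.0 / 60.0,
                        od0: float | None = None) -> BatchGrowthEstimate:
    """Maximum exponential growth rate and lag from an OD600 series.

    Scans every contiguous window spanning at least ``min_window`` hours,
    fits ln(OD) against time by OLS and keeps the window with the
    largest slope.  The lag is where the fitted exponential extension
    equals the inoculum OD (``od0``, default the first observation):
    lag = (ln(od0) - intercept) / rate.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(od, dtype=float)
    if np.any(y <= 0):
        raise ValueError("OD values must be positive")
    if t.size < 3 or t[-1] - t[0] < min_window:
        raise ValueError("series shorter than the minimum window")
    ly = np.log(y)
    n = t.size
    best = None  # (slope, intercept, i, j, r2)
    for i in range(n - 2):
        for j in range(i + 2, n):
            if t[j] - t[i] < min_window:
                continue
            tt, yy = t[i:j + 1], ly[i:j + 1]
            A = np.vstack([tt, np.ones_like(tt)]).T
            (slope, intercept), res, *_ = np.linalg.lstsq(A, yy, rcond=None)
            sst = float(np.sum((yy - yy.mean()) ** 2))
            ssr = float(res[0]) if res.size else float(np.sum((A @ [slope, intercept] - yy) ** 2))
            r2 = 1.0 - ssr / sst if sst > 0 else 1.0
            if best is None or slope > best[0] + 1e-15:
                best = (slope, intercept, i, j, r2)
    rate, intercept, i, j, r2 = best
    base = float(y[0]) if od0 is None else float(od0)
    lag = (math.log(base) - intercept) / rate if rate > 0 else np.nan
    lag = max(lag, 0.0) if np.isfinite(lag) else lag
    return BatchGrowthEstimate(rate=float(rate), lag=float(lag),
                               window=(float(t[i]), float(t[j])), r_squared=r2)


class BatchGrowthModel:
    """OD600 batch-growth model (sliding-window exponential fit)."""

    def __init__(self, time, od, time_unit: str = "h"):
        t = np.asarray(time, dtype=float)
        if time_unit == "min":
            t = t / 60.0
        self.time = t
        self.od = np.asarray(od, dtype=float)

    def fit(self, min_window: float = 100.0 / 60.0,
            od0: float | None = None) -> BatchGrowthEstimate:
        return batch_growth_params(self.time, self.od, min_window=min_window, od0=od0)
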