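"""Interrupted time series models for 3-hourly traffic counts.

One quasi-Poisson GLM is fitted per daily time window (and per vehicle
class/site), regressing the 3-h count on

* an intercept,
* a linear trend ``t`` in days since the series origin,
* a step ``open`` that is 1 from the facility opening date onward
  (inclusive),
* six day-of-week contrasts (Monday reference), and
* two sine/cosine harmonic pairs with a 12-month (365.25-day) period
  capturing long-term seasonal structure.

The model is log-linked, so the opening coefficient exponentiates to a rate
ratio and is reported as a percent change with a Wald 95% CI.  Dispersion is
the Pearson chi-square over residual degrees of freedom, and all standard
errors carry the sqrt-dispersion inflation (quasi-likelihood inference; no
multiplicity adjustment is applied across windows).

Attribution: for post-opening windows the warehouse-attributable flow is the
difference between the fitted prediction and the counterfactual prediction
with the opening indicator switched off, all other covariates at their
observed values — under the log link, ``fitted x (1 - exp(-beta_open))`` per
window — averaged separately over weekday and weekend windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
import statsmodels.api as sm

HARMONIC_PERIOD_DAYS = 365.25
DEFAULT_OPENING = date(2018, 10, 1)
Z95 = 1.96  # normal quantile used for every reported 95% interval

DOW_NAMES = ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]

DESIGN_COLUMNS = ["intercept", "t", "open",
                  "dow_tue", "dow_wed", "dow_thu", "dow_fri", "dow_sat", "dow_sun",
                  "sin1", "cos1", "sin2", "cos2"]


@dataclass(frozen=True)
class ITSSpec:
    """Design choices for one interrupted-time-series model."""

    opening_date: date = DEFAULT_OPENING
    harmonic_period_days: float = HARMONIC_PERIOD_DAYS


def build_design(dates, spec: ITSSpec = ITSSpec()) -> pd.DataFrame:
    """Design matrix for a series of window-start timestamps.

    The time origin is the first observed day; the opening indicator is 1 on
    the opening date itself and after.  Raises if the series lies entirely on
    one side of the opening (the step would be inestimable).
    """
    idx = pd.DatetimeIndex(pd.to_datetime(dates))
    if len(idx) == 0:
        raise ValueError("no dates supplied")
    days = idx.normalize()
    t = (days - days[0]).days.to_numpy(dtype=float)
    open_ = (days >= pd.Timestamp(spec.opening_date)).astype(float)
    if open_.min() == open_.max():
        raise ValueError("series is all pre- or all post-opening; "
                         "the intervention effect is inestimable")
    w = 2 * np.pi * t / spec.harmonic_period_days
    X = pd.DataFrame({"intercept": 1.0, "t": t, "open": open_}, index=idx)
    dow = idx.dayofweek
    for d in range(1, 7):  # Monday (0) is the reference level
        X[f"dow_{DOW_NAMES[d]}"] = (dow == d).astype(float)
    X["sin1"], X["cos1"] = np.sin(w), np.cos(w)
    X["sin2"], X["cos2"] = np.sin(2 * w), np.cos(2 * w)
    return X


@dataclass
class ITSFit:
    """A fitted per-window quasi-Poisson model."""

    params: pd.Series
    cov: pd.DataFrame
    dispersion: float
    n: int
    design: pd.DataFrame
    counts: np.ndarray
    fitted: np.ndarray
    converged: bool
    lag1_autocorr: float

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def fit_its(counts, design: pd.DataFrame, min_rows: int = 60) -> ITSFit:
    """Fit the quasi-Poisson ITS model by IRLS.

    ``counts`` are non-negative 3-h window totals aligned with ``design``
    rows.  Standard errors and the covariance are scaled by the Pearson
    dispersion.  A lag-1 Pearson-residual autocorrelation is reported as a
    diagnostic (inference itself is plain quasi-Poisson).
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if len(y) != len(design):
        raise ValueError("counts and design length mismatch")
    if len(y) < min_rows:
        raise ValueError(f"need at least {min_rows} windows, got {len(y)}")
    model = sm.GLM(y, design, family=sm.families.Poisson())
    # fit at unit scale, then apply the Pearson dispersion to the covariance;
    # the point estimates are scale-free and this stays finite on perfect fits
    res = model.fit(scale=1.0)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge after {res.fit_history['iteration']} "
                           f"iterations; deviance {res.deviance:.3g}")
    dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
    cov = res.cov_params() * dispersion
    resid = np.asarray(res.resid_pearson)
    denom = float(np.sum(resid ** 2))
    lag1 = float(np.sum(resid[1:] * resid[:-1]) / denom) if denom > 0 else 0.0
    return ITSFit(params=res.params, cov=cov, dispersion=dispersion,
                  n=len(y), design=design, counts=y, fitted=np.asarray(res.fittedvalues),
                  converged=bool(res.converged), lag1_autocorr=lag1)


@dataclass(frozen=True)
class PercentChange:
    """Exponentiated opening effect: percent change with Wald 95% CI."""

    estimate: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self):
        if not (self.ci_lower <= self.estimate <= self.ci_upper):
            raise ValueError("interval must bracket the estimate")


def percent_change_from_coef(beta: float, se: float, z: float = Z95) -> PercentChange:
    """Map a log-scale step coefficient and its SE to a percent change."""
    est = (np.exp(beta) - 1.0) * 100.0
    lo = (np.exp(beta - z * se) - 1.0) * 100.0
    hi = (np.exp(beta + z * se) - 1.0) * 100.0
    return PercentChange(float(est), float(lo), float(hi))


def percent_change(fit: ITSFit) -> PercentChange:
    """Percent traffic change attributable to the opening, with 95% CI."""
    return percent_change_from_coef(float(fit.params["open"]), float(fit.bse["open"]))


@dataclass(frozen=True)
class AttributableChange:
    """Mean attributable change in one window's counts, by day type."""

    day_type: str          # "weekday" | "weekend" | "pooled"
    delta_count: float     # vehicles per 3-h window
    se_count: float
    n_windows: int

    @property
    def delta_per_hour(self) -> float:
        return self.delta_count / 3.0

    @property
    def se_per_hour(self) -> float:
        return self.se_count / 3.0


def _day_type_mask(idx: pd.DatetimeIndex, day_type: str) -> np.ndarray:
    dow = idx.dayofweek
    if day_type == "weekday":
        return (dow < 5).to_numpy() if hasattr(dow < 5, "to_numpy") else np.asarray(dow < 5)
    if day_type == "weekend":
        return np.asarray(dow >= 5)
    if day_type == "pooled":
        return np.ones(len(idx), dtype=bool)
    raise ValueError(f"unknown day_type {day_type!r}")


def attribute_flows(fit: ITSFit, day_type: str = "pooled",
                    post_period: tuple | None = None) -> AttributableChange:
    """Average warehouse-attributable count change over post-opening windows.

    Per window the change is prediction(open=1) - prediction(open=0) with all
    other covariates observed; under the log link that is
    fitted x (1 - exp(-beta_open)).  The standard error of the average comes
    from the delta method on the coefficient covariance.  An empty day-type
    subset yields a flagged empty result (n_windows = 0, NaN change).
    """
    X = fit.design
    idx = pd.DatetimeIndex(X.index)
    mask = (X["open"].to_numpy() == 1.0) & _day_type_mask(idx, day_type)
    if post_period is not None:
        lo, hi = pd.Timestamp(post_period[0]), pd.Timestamp(post_period[1])
        mask &= np.asarray(idx >= lo) & np.asarray(idx < hi)
    if not mask.any():
        return AttributableChange(day_type, float("nan"), float("nan"), 0)
    Xm = X.to_numpy()[mask]
    beta = fit.params.to_numpy()
    j = list(X.columns).index("open")
    eta = Xm @ beta
    mu1 = np.exp(eta)                       # fitted, opening on
    mu0 = np.exp(eta - beta[j])             # counterfactual, opening off
    delta = mu1 - mu0
    # gradient of mean(mu1 - mu0) wrt beta
    e_j = np.zeros_like(beta)
    e_j[j] = 1.0
    grad = (mu1[:, None] * Xm - mu0[:, None] * (Xm - e_j)).mean(axis=0)
    var = float(grad @ fit.cov.to_numpy() @ grad)
    return AttributableChange(day_type, float(delta.mean()), float(np.sqrt(max(var, 0.0))),
                              int(mask.sum()))


def fit_window_models(counts3h: pd.DataFrame, count_col: str,
                      spec: ITSSpec = ITSSpec(), min_rows: int = 60) -> dict[int, ITSFit]:
    """Fit one ITS model per daily 3-h window (8 models).

    ``counts3h`` is a :func:`trafficimpact.ingest.compute_flows` frame at 3-h
    resolution; excluded windows are dropped, not imputed.
    """
    fits: dict[int, ITSFit] = {}
    idx = pd.DatetimeIndex(counts3h.index)
    kept = counts3h.loc[~counts3h["excluded"].to_numpy()]
    for hour in range(0, 24, 3):
        sub = kept[pd.DatetimeIndex(kept.index).hour == hour]
        X = build_design(sub.index, spec)
        fits[hour] = fit_its(sub[count_col].to_numpy(), X, min_rows=min_rows)
    return fits


def percent_change_table(fits_by_class: dict[str, dict[int, ITSFit]]) -> pd.DataFrame:
    """Percent-change summary across classes and windows (one row per model).

    Shape of the per-window effect plot: class, window start hour, % change,
    CI bounds, and the post-opening mean count for that window.
    """
    rows = []
    for cls, fits in fits_by_class.items():
        for hour, fit in sorted(fits.items()):
            pc = percent_change(fit)
            post = fit.counts[fit.design["open"].to_numpy() == 1.0]
            rows.append({"class": cls, "window_start_hour": hour,
                         "percent_change": pc.estimate, "ci_lower": pc.ci_lower,
                         "ci_upper": pc.ci_upper,
                         "post_mean_count": float(post.mean()) if len(post) else float("nan"),
                         "dispersion": fit.dispersion, "lag1_autocorr": fit.lag1_autocorr})
    return pd.DataFrame(rows)


def attribution_table(fits_by_class: dict[str, dict[int, ITSFit]],
                      day_types: tuple[str, ...] = ("weekday", "weekend"),
                      external: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attributable flow changes by class, window, and day type.

    ``external`` optionally supplies user-provided predictions (e.g. from a
    regulatory assessment) keyed on class/window_start_hour/day_type for
    side-by-side comparison; it is merged, never computed.
    """
    rows = []
    for cls, fits in fits_by_class.items():
        for hour, fit in sorted(fits.items()):
            for dt in day_types:
                ch = attribute_flows(fit, dt)
                rows.append({"class": cls, "window_start_hour": hour, "day_type": dt,
                             "delta_count_3h": ch.delta_count, "se_count_3h": ch.se_count,
                             "delta_per_hour": ch.delta_per_hour,
                             "se_per_hour": ch.se_per_hour, "n_windows": ch.n_windows})
    table = pd.DataFrame(rows)
    if external is not None:
        table = table.merge(external, on=["class", "window_start_hour", "day_type"],
                            how="left")
    return table
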