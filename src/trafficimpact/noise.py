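"""Traffic -> sound-intensity regression and per-100-vehicles slopes.

The 15-min sound-intensity ratio is modelled as linear in classified flows,

    I(t)/I0 = lambda_car Q_car(t) + lambda_tr Q_tr(t) + s(t)          (segregated)
    I(t)/I0 = lambda_tot Q_tot(t) + s(t)                              (total)

with s(t) a slow instrument-drift term (natural cubic spline, 3 df, plus
intercept) and Gamma-distributed errors.  The default link is the identity:
the model is written additively in the flows, and the reported slope formula
below presumes dI/dQ = lambda x I0, which only holds under the identity
link.  A log link is available behind a flag for sensitivity analysis.

The lambda coefficients (units: hours, since Q is in 1/h and I/I0 is
dimensionless) convert to level slopes at each site's median intensity I50:

    dLeq/dQ = 10 lambda I0/I50, reported per 100 vehicles/h.

Note this reporting formula is used exactly as conventionally printed, i.e.
without the 1/ln(10) factor a strict derivative of 10 log10 would carry; the
resulting numbers are the published convention for this quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats

import warnings

DRIFT_DF = 3


@dataclass(frozen=True)
class LambdaEstimate:
    value: float          # h
    ci_lower: float
    ci_upper: float
    se: float
    p_value: float

    def __post_init__(self):
        if not (self.ci_lower <= self.value <= self.ci_upper):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass
class NoiseModelFit:
    """Fitted traffic-noise model for one site."""

    lambdas: dict[str, LambdaEstimate]   # keys among "car", "tr", "tot"
    spline_coefs: np.ndarray             # drift-basis coefficients (basis spans the constant)
    link: str
    n: int
    median_intensity_ratio: float        # I50/I0 over the fitted series
    median_leq: float                    # dBA
    dispersion: float
    fitted: np.ndarray = None            # fitted intensity ratios
    observed: np.ndarray = None


def quantile_residuals(fit: NoiseModelFit) -> np.ndarray:
    """Quantile residuals for the Gamma fit, standard normal if well specified.

    Each residual is the normal quantile of the fitted Gamma CDF at the
    observation (shape 1/dispersion, scale fitted x dispersion).  The
    response is continuous, so no randomization is involved; skewed or
    heavy-tailed residuals indicate a misspecified mean or error model.
    """
    if fit.fitted is None or not np.isfinite(fit.dispersion) or fit.dispersion < 1e-12:
        # a numerically perfect fit has no residual distribution to assess
        raise ValueError("fit carries no residual information")
    shape = 1.0 / fit.dispersion
    cdf = stats.gamma.cdf(fit.observed, a=shape, scale=fit.fitted * fit.dispersion)
    eps = np.finfo(float).tiny
    return stats.norm.ppf(np.clip(cdf, eps, 1 - 1e-16))


def _drift_basis(t: np.ndarray, df: int = DRIFT_DF) -> np.ndarray:
    """Natural cubic spline basis for s(t) spanning the deployment.

    The df basis columns span the constant, so s(t) absorbs the baseline
    intensity and no separate intercept is added.
    """
    return np.asarray(dmatrix("cr(t, df=df) - 1", {"t": t, "df": df}))


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError("rank-deficient design; collinear columns include "
                         f"{X.columns[i]!r} and {X.columns[j]!r}")


def _fit(I_ratio: np.ndarray, flows: dict[str, np.ndarray], t: np.ndarray,
         drift_df: int, link: str) -> NoiseModelFit:
    I_ratio = np.asarray(I_ratio, dtype=float)
    if np.any(~np.isfinite(I_ratio)) or np.any(I_ratio <= 0):
        raise ValueError("sound intensities must be positive and finite")
    if len(I_ratio) < 10:
        raise ValueError("need at least 10 windows to fit the noise model")
    basis = _drift_basis(np.asarray(t, dtype=float), drift_df)
    X = pd.DataFrame({f"q_{k}": np.asarray(v, dtype=float) for k, v in flows.items()})
    for col in range(basis.shape[1]):
        X[f"s{col}"] = basis[:, col]
    _check_rank(X)
    links = {"identity": sm.families.links.Identity(), "log": sm.families.links.Log()}
    if link not in links:
        raise ValueError(f"link must be one of {sorted(links)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identity link is outside Gamma's canonical domain
        # unit-scale IRLS plus a Pearson moment estimate of the dispersion;
        # stays finite when the model fits the data exactly
        res = sm.GLM(I_ratio, X, family=sm.families.Gamma(link=links[link])).fit(scale=1.0)
    dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
    bse = np.sqrt(np.diag(res.cov_params()) * dispersion)
    bse = pd.Series(bse, index=res.params.index)
    lambdas = {}
    for k in flows:
        est, se = float(res.params[f"q_{k}"]), float(bse[f"q_{k}"])
        z = est / se if se > 0 else np.inf * np.sign(est)
        lambdas[k] = LambdaEstimate(est, est - 1.96 * se, est + 1.96 * se, se,
                                    float(2 * stats.norm.sf(abs(z))))
    med = float(np.median(I_ratio))
    return NoiseModelFit(lambdas=lambdas,
                         spline_coefs=res.params.to_numpy()[len(flows):],
                         link=link, n=len(I_ratio), median_intensity_ratio=med,
                         median_leq=float(10.0 * np.log10(med)),
                         dispersion=dispersion,
                         fitted=np.asarray(res.fittedvalues), observed=I_ratio)


def fit_noise_model(I_ratio, q_car, q_tr, t=None, drift_df: int = DRIFT_DF,
                    link: str = "identity") -> NoiseModelFit:
    """Fit the segregated-flow model I/I0 ~ Q_car + Q_tr + s(t).

    ``t`` is time in days (or any monotone coordinate) for the drift spline;
    defaults to the observation index.  Flows are vehicles/h.
    """
    n = len(np.asarray(I_ratio))
    t = np.arange(n, dtype=float) if t is None else t
    return _fit(I_ratio, {"car": q_car, "tr": q_tr}, t, drift_df, link)


def fit_noise_model_total(I_ratio, q_tot, t=None, drift_df: int = DRIFT_DF,
                          link: str = "identity") -> NoiseModelFit:
    """Fit the total-flow model I/I0 ~ Q_tot + s(t)."""
    q = np.asarray(q_tot, dtype=float)
    if np.all(q == 0):
        raise ValueError("total flow is identically zero; lambda_tot inestimable")
    n = len(np.asarray(I_ratio))
    t = np.arange(n, dtype=float) if t is None else t
    return _fit(I_ratio, {"tot": q}, t, drift_df, link)


def slope_from_lambda(lam: float, median_leq: float) -> float:
    """Level slope 10 x lambda x I0/I50, expressed per 100 vehicles/h.

    ``lam`` in hours, ``median_leq`` in dBA; result in dBA/(100 h^-1).
    """
    return 10.0 * lam * 10.0 ** (-median_leq / 10.0) * 100.0


@dataclass(frozen=True)
class SlopeCoefficients:
    """dLeq/dQ per vehicle class at a site, in dBA per 100 vehicles/h."""

    slopes: dict[str, float]
    median_leq: float

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.slopes.items()}


def slope_coefficients(fit: NoiseModelFit) -> SlopeCoefficients:
    """Per-class level slopes at the fit's median intensity."""
    return SlopeCoefficients(
        slopes={k: slope_from_lambda(est.value, fit.median_leq)
                for k, est in fit.lambdas.items()},
        median_leq=fit.median_leq)


def lambda_ratio(fit: NoiseModelFit) -> float:
    """Truck-to-car intensity-coefficient ratio lambda_tr / lambda_car."""
    if "tr" not in fit.lambdas or "car" not in fit.lambdas:
        raise ValueError("ratio requires a segregated-flow fit")
    car = fit.lambdas["car"].value
    if car == 0:
        raise ZeroDivisionError("lambda_car is zero; ratio undefined")
    return fit.lambdas["tr"].value / car


def collinearity(q_car, q_tr) -> float:
    """Pearson correlation between the car and truck flow series."""
    a = np.asarray(q_car, dtype=float)
    b = np.asarray(q_tr, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length series with at least 3 points")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(stats.pearsonr(a, b).statistic)


def delta_intensity(lambda_car: float, lambda_tr: float,
                    dq_car: float, dq_tr: float) -> float:
    """First-order intensity-ratio change for flow changes in vehicles/h.

    Because the intensity model is linear in the flows this "Taylor" form is
    exact, not just first-order.
    """
    return lambda_car * dq_car + lambda_tr * dq_tr


def delta_leq(slopes: SlopeCoefficients | dict[str, float], dq: dict[str, float]) -> float:
    """Level change from flow changes, dBA.

    ``slopes`` in dBA/(100 h^-1) keyed by class; ``dq`` in vehicles/h with
    matching keys.  Uses the median-intensity approximation baked into the
    slopes.
    """
    table = slopes.slopes if isinstance(slopes, SlopeCoefficients) else slopes
    missing = set(dq) - set(table)
    if missing:
        raise KeyError(f"no slope for class(es) {sorted(missing)}")
    return float(sum(table[k] * dq[k] / 100.0 for k in dq))


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def coefficient_table(fits: dict[str, NoiseModelFit]) -> pd.DataFrame:
    """Mobile-source coefficient table across sites and model forms.

    One row per site x model (segregated or total): lambda estimates with 95%
    CIs and significance stars (p < 0.05 "*", p < 0.001 "***"), and the
    corresponding level slopes per 100 vehicles/h (1 d.p.).
    """
    rows = []
    for site, fit in fits.items():
        slopes = slope_coefficients(fit)
        model = "Q_tot" if "tot" in fit.lambdas else "Q_tr + Q_car"
        row: dict[str, object] = {"site": site, "model": model, "link": fit.link,
                                  "n": fit.n, "median_leq": fit.median_leq}
        for k, est in fit.lambdas.items():
            row[f"lambda_{k}"] = est.value
            row[f"lambda_{k}_ci"] = f"({est.ci_lower:,.0f}, {est.ci_upper:,.0f})"
            row[f"lambda_{k}_sig"] = _stars(est.p_value)
            row[f"slope_{k}"] = round(slopes.slopes[k], 1)
        rows.append(row)
    return pd.DataFrame(rows)
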