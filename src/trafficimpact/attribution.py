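"""Convert attributable traffic changes into predicted BC and noise increases.

The interrupted-time-series stage yields, per site, 3-h window, and day type,
the warehouse-attributable change in truck and car flow.  Those changes are
converted with site-specific mobile-source coefficients:

* black carbon: dBC = alpha_tr dQ_tr/100 + alpha_car dQ_car/100, with the
  alphas in ug/m^3 per 100 vehicles/h (published coefficients consumed as
  inputs, applied as linear multipliers);
* noise: dLeq = slope_tr dQ_tr/100 + slope_car dQ_car/100, with the slopes
  in dBA per 100 vehicles/h derived from the fitted intensity coefficients
  at the site's median level.

All flow changes must be in vehicles per hour; uncertainty is propagated
linearly from the attributable-flow standard errors (classes treated as
independent).  The summary is the arithmetic mean and SD across all
site x window x day-type cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .noise import delta_leq


@dataclass(frozen=True)
class EmissionCoefficients:
    """Site-matched BC and noise coefficients per 100 vehicles/h."""

    site: str
    alpha_tr: float      # ug/m^3 per 100 trucks/h
    alpha_car: float     # ug/m^3 per 100 cars/h
    slope_tr: float      # dBA per 100 trucks/h
    slope_car: float     # dBA per 100 cars/h


@dataclass(frozen=True)
class FlowChange:
    """Attributable flow change for one site x window x day-type cell."""

    site: str
    window_start_hour: int
    day_type: str
    dq_tr: float         # vehicles/h
    dq_car: float        # vehicles/h
    se_tr: float = 0.0
    se_car: float = 0.0
    units: str = "per_hour"

    @property
    def dq_tot(self) -> float:
        return self.dq_tr + self.dq_car


@dataclass(frozen=True)
class PollutantIncrease:
    site: str
    window_start_hour: int
    day_type: str
    d_bc: float          # ug/m^3
    d_leq: float         # dBA
    se_bc: float
    se_leq: float


def _require_hourly(change: FlowChange) -> None:
    if change.units != "per_hour":
        raise ValueError(f"flow changes must be in vehicles/h, got units={change.units!r} "
                         "(convert 3-h window counts before attribution)")


def bc_increase(change: FlowChange, coeffs: EmissionCoefficients) -> tuple[float, float]:
    """Predicted BC increase (ug/m^3) and its propagated standard error."""
    _require_hourly(change)
    d = coeffs.alpha_tr * change.dq_tr / 100.0 + coeffs.alpha_car * change.dq_car / 100.0
    se = np.hypot(coeffs.alpha_tr * change.se_tr / 100.0,
                  coeffs.alpha_car * change.se_car / 100.0)
    return float(d), float(se)


def noise_increase(change: FlowChange, coeffs: EmissionCoefficients) -> tuple[float, float]:
    """Predicted equivalent-level increase (dBA) and standard error."""
    _require_hourly(change)
    slopes = {"tr": coeffs.slope_tr, "car": coeffs.slope_car}
    d = delta_leq(slopes, {"tr": change.dq_tr, "car": change.dq_car})
    se = np.hypot(coeffs.slope_tr * change.se_tr / 100.0,
                  coeffs.slope_car * change.se_car / 100.0)
    return float(d), float(se)


def pollutant_increase(change: FlowChange, coeffs: EmissionCoefficients) -> PollutantIncrease:
    if coeffs.site != change.site:
        raise ValueError(f"coefficients for {coeffs.site!r} applied to {change.site!r}")
    d_bc, se_bc = bc_increase(change, coeffs)
    d_leq, se_leq = noise_increase(change, coeffs)
    return PollutantIncrease(change.site, change.window_start_hour, change.day_type,
                             d_bc, d_leq, se_bc, se_leq)


@dataclass(frozen=True)
class IncreaseSummary:
    mean_bc: float
    sd_bc: float
    mean_leq: float
    sd_leq: float
    n_cells: int


def summarize_increases(increases: list[PollutantIncrease] | pd.DataFrame) -> IncreaseSummary:
    """Mean and SD of the predicted increases across all cells."""
    if isinstance(increases, pd.DataFrame):
        bc = increases["d_bc"].to_numpy(dtype=float)
        leq = increases["d_leq"].to_numpy(dtype=float)
    else:
        bc = np.array([i.d_bc for i in increases], dtype=float)
        leq = np.array([i.d_leq for i in increases], dtype=float)
    if len(bc) < 2:
        raise ValueError("need at least 2 cells to summarize")
    return IncreaseSummary(float(bc.mean()), float(bc.std(ddof=1)),
                           float(leq.mean()), float(leq.std(ddof=1)), len(bc))


def increase_table(increases: list[PollutantIncrease]) -> pd.DataFrame:
    """Diurnal-profile table: one row per site x window x day type."""
    return pd.DataFrame([{
        "site": i.site, "window_start_hour": i.window_start_hour, "day_type": i.day_type,
        "d_bc_ugm3": i.d_bc, "se_bc": i.se_bc, "d_leq_dba": i.d_leq, "se_leq": i.se_leq,
    } for i in increases]).sort_values(["site", "day_type", "window_start_hour"]
                                       ).reset_index(drop=True)


def read_coefficients_csv(path) -> dict[str, EmissionCoefficients]:
    """Load per-site coefficients (columns site,alpha_tr,alpha_car,slope_tr,slope_car)."""
    df = pd.read_csv(path)
    for col in ("site", "alpha_tr", "alpha_car", "slope_tr", "slope_car"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return {str(r.site): EmissionCoefficients(str(r.site), float(r.alpha_tr),
                                              float(r.alpha_car), float(r.slope_tr),
                                              float(r.slope_car))
            for r in df.itertuples()}


def write_coefficients_csv(coeffs: dict[str, EmissionCoefficients], path) -> None:
    pd.DataFrame([{"site": c.site, "alpha_tr": c.alpha_tr, "alpha_car": c.alpha_car,
                   "slope_tr": c.slope_tr, "slope_car": c.slope_car}
                  for c in coeffs.values()]).to_csv(path, index=False)


def attribute_increases(flow_changes: pd.DataFrame,
                        coeffs: dict[str, EmissionCoefficients]) -> list[PollutantIncrease]:
    """Apply site coefficients to a table of attributable flow changes.

    Expects columns ``site, window_start_hour, day_type, dq_tr, dq_car`` and
    optional ``se_tr, se_car``, flows in vehicles/h.
    """
    increases = []
    for r in flow_changes.itertuples():
        site = str(r.site)
        if site not in coeffs:
            raise KeyError(f"no coefficients for site {site!r}")
        change = FlowChange(site, int(r.window_start_hour), str(r.day_type),
                            float(r.dq_tr), float(r.dq_car),
                            float(getattr(r, "se_tr", 0.0)), float(getattr(r, "se_car", 0.0)))
        increases.append(pollutant_increase(change, coeffs[site]))
    return increases
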