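"""End-to-end pipeline glue: events -> flows -> ITS -> pollutant increases.

These helpers wire the modules together the way a full analysis runs: window
the radar events, fit per-window interrupted time series for trucks and cars,
average the attributable flow changes by day type, and convert them to
predicted BC and noise increases with site coefficients.
"""

from __future__ import annotations

import pandas as pd

from . import attribution, its
from .ingest import compute_flows
from .synthetic import ScenarioConfig, generate_vehicle_events

DAY_TYPES = ("weekday", "weekend")


def fit_traffic_models(counts3h: pd.DataFrame, spec: its.ITSSpec = its.ITSSpec(),
                       min_rows: int = 60) -> dict[str, dict[int, its.ITSFit]]:
    """Per-window ITS fits for trucks and cars (16 models)."""
    return {cls: its.fit_window_models(counts3h, cls, spec, min_rows)
            for cls in ("trucks", "cars")}


def attributable_flow_table(fits_by_class: dict[str, dict[int, its.ITSFit]], site: str,
                            day_types: tuple[str, ...] = DAY_TYPES) -> pd.DataFrame:
    """Attributable truck/car flow changes in vehicles/h per window x day type."""
    rows = []
    for hour in sorted(fits_by_class["trucks"]):
        for dt in day_types:
            tr = its.attribute_flows(fits_by_class["trucks"][hour], dt)
            car = its.attribute_flows(fits_by_class["cars"][hour], dt)
            rows.append({"site": site, "window_start_hour": hour, "day_type": dt,
                         "dq_tr": tr.delta_per_hour, "se_tr": tr.se_per_hour,
                         "dq_car": car.delta_per_hour, "se_car": car.se_per_hour})
    return pd.DataFrame(rows)


def run_scenario(config: ScenarioConfig,
                 coeffs: dict[str, attribution.EmissionCoefficients],
                 spec: its.ITSSpec | None = None,
                 day_types: tuple[str, ...] = DAY_TYPES):
    """Simulate a scenario and push it through the whole pipeline.

    Returns (increase summary, increase table, attributable-flow table,
    fits by class).
    """
    if spec is None:
        spec = its.ITSSpec(opening_date=config.opening_date)
    events = generate_vehicle_events(config)
    span = (pd.Timestamp(config.start_date), pd.Timestamp(config.end_date))
    counts3h = compute_flows(events, "3h", span=span)
    fits = fit_traffic_models(counts3h, spec)
    flow_changes = attributable_flow_table(fits, config.site, day_types)
    increases = attribution.attribute_increases(flow_changes, coeffs)
    summary = attribution.summarize_increases(increases)
    return summary, attribution.increase_table(increases), flow_changes, fits
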