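"""Growth-rate transfer from forecast counts to adopter-area projections.

Forecast counts from comparison (non-adopter) areas are converted into
cumulative growth rates anchored at a baseline year — two years before policy
adoption, to exclude announcement effects — and those rates are applied
multiplicatively to an adopter area's own baseline count. Interval bounds
transfer through the same multiplicative map as the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .zones import DissolvedZone

__all__ = [
    "GrowthSchedule",
    "AdopterProjection",
    "baseline_year",
    "to_growth_schedule",
    "apply_growth",
    "scale_zone_counts",
]


@dataclass
class GrowthSchedule:
    """Cumulative growth rates (proportions) per future year, with 95% bounds."""

    baseline_year: int
    baseline_count: float
    rates: pd.DataFrame  # year, rate_est, rate_lo95, rate_hi95

    def __post_init__(self):
        r = self.rates
        bad = ~((r["rate_lo95"] <= r["rate_est"]) & (r["rate_est"] <= r["rate_hi95"]))
        if bad.any():
            raise ValueError("growth-rate bounds are not ordered")

    def rate_for(self, year: int) -> tuple:
        if year == self.baseline_year:
            return (0.0, 0.0, 0.0)
        row = self.rates.loc[self.rates["year"] == year]
        if row.empty:
            raise KeyError(f"no growth rate for year {year}")
        return tuple(row.iloc[0][["rate_est", "rate_lo95", "rate_hi95"]])


@dataclass
class AdopterProjection:
    area_id: str
    baseline_year: int
    baseline_count: float
    counts: pd.DataFrame  # year, count_est, count_lo95, count_hi95


def baseline_year(adoption_year: int) -> int:
    """Baseline year = adoption year minus two (pre-announcement anchor)."""
    return adoption_year - 2


def to_growth_schedule(forecasts: pd.DataFrame, baseline_count: float, base_year: int) -> GrowthSchedule:
    """Cumulative growth rate per year: count / baseline_count - 1.

    ``forecasts`` columns: year, mean, lower95, upper95. The same map applies
    to the estimate and both interval bounds.
    """
    if baseline_count <= 0:
        raise ValueError("baseline_count must be positive")
    rates = pd.DataFrame(
        {
            "year": forecasts["year"].astype(int),
            "rate_est": forecasts["mean"] / baseline_count - 1.0,
            "rate_lo95": forecasts["lower95"] / baseline_count - 1.0,
            "rate_hi95": forecasts["upper95"] / baseline_count - 1.0,
        }
    )
    return GrowthSchedule(base_year, float(baseline_count), rates)


def apply_growth(baseline_count: float, schedule: GrowthSchedule, area_id: str = "area") -> AdopterProjection:
    """Projected counts: baseline_count * (1 + rate), estimate and bounds."""
    r = schedule.rates
    counts = pd.DataFrame(
        {
            "year": r["year"],
            "count_est": baseline_count * (1.0 + r["rate_est"]),
            "count_lo95": baseline_count * (1.0 + r["rate_lo95"]),
            "count_hi95": baseline_count * (1.0 + r["rate_hi95"]),
        }
    )
    return AdopterProjection(area_id, schedule.baseline_year, float(baseline_count), counts)


def scale_zone_counts(zones: list, schedule: GrowthSchedule, year: int) -> list:
    """Scale every zone's outlet count by the same year-specific growth rate.

    Growth is uniform within an area (the method does not model within-area
    heterogeneity), so zone totals stay consistent with ``apply_growth`` on
    the summed baseline.
    """
    rate, _, _ = schedule.rate_for(year)
    return [
        DissolvedZone(z.class_label, z.geometry, count_k=z.count_k * (1.0 + rate))
        for z in zones
    ]
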