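"""Trend indices: scalar summaries of a sector's rate evolution over the span.

The default index is the ordinary-least-squares slope of the dispute rate
on calendar year, scaled by 100 (percentage points of dispute rate per
year).  It uses every observed year of the series, is zero for a constant
series and inherits the sign of the underlying linear trend.  Two
endpoint/ratio-based alternatives are provided for sensitivity checks;
the method used is always recorded in the result.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .data_io import RateTable

METHODS = ("ols_slope_scaled", "total_relative_change", "mean_link_relative")


@dataclasses.dataclass(frozen=True)
class TrendResult:
    sector: str
    method: str
    index: float
    slope: float | None = None
    intercept: float | None = None

    @property
    def classification(self) -> str:
        if self.index > 0:
            return "increasing"
        if self.index < 0:
            return "decreasing"
        return "flat"


def trend_index(
    years: Sequence[int],
    values: Sequence[float],
    method: str = "ols_slope_scaled",
    sector: str = "",
) -> TrendResult:
    """Trend index of one yearly rate series (needs >= 3 observed years).

    ols_slope_scaled
        100 x OLS slope of rate on year.
    total_relative_change
        (last - first) / first; errors on a zero first value.
    mean_link_relative
        mean of successive year-over-year ratios, minus 1; errors on a
        zero intermediate value (undefined ratio).
    """
    yr = np.asarray(years, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = ~np.isnan(v)
    yr, v = yr[keep], v[keep]
    if v.size < 3:
        raise ValueError(f"trend needs at least 3 observed years, got {v.size}")
    order = np.argsort(yr)
    yr, v = yr[order], v[order]
    if method == "ols_slope_scaled":
        slope, intercept = np.polyfit(yr, v, 1)
        return TrendResult(sector, method, float(100.0 * slope), float(slope), float(intercept))
    if method == "total_relative_change":
        if v[0] == 0.0:
            raise ValueError("total_relative_change undefined: first value is zero")
        return TrendResult(sector, method, float((v[-1] - v[0]) / v[0]))
    if method == "mean_link_relative":
        if (v[:-1] == 0.0).any():
            raise ValueError("mean_link_relative undefined: zero value inside the series")
        return TrendResult(sector, method, float((v[1:] / v[:-1]).mean() - 1.0))
    raise ValueError(f"unknown trend method {method!r}; choose from {METHODS}")


def trend_report(rates: RateTable, method: str = "ols_slope_scaled") -> pd.DataFrame:
    """Per-sector trend indices with sign classification."""
    rows = []
    frame = rates.rates
    for sector in rates.sectors:
        series = frame.loc[sector]
        result = trend_index(series.index.to_numpy(), series.to_numpy(), method, sector)
        rows.append(
            {
                "sector": sector,
                "method": result.method,
                "index": result.index,
                "classification": result.classification,
            }
        )
    return pd.DataFrame(rows).set_index("sector")
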