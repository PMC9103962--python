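"""Period split and descriptive statistics of dispute-rate series.

The analysis contrasts two periods around a regulatory cutoff year (for the
ICQRF record, the 2004 entry into force of the EU food-hygiene package):
years <= cutoff form period 1, years > cutoff period 2.  Summaries report
mean, sample standard deviation (n-1 denominator), median, quartiles
(linear interpolation) and Tukey 1.5 x IQR whisker fences for boxplots.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .data_io import RateTable

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PeriodDesign:
    """Two-period split at a cutoff year (years <= cutoff are period 1)."""

    cutoff_year: int
    labels: tuple[str, str] = ("pre", "post")


@dataclasses.dataclass(frozen=True)
class PeriodSummary:
    sector: str
    period: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    whisker_low: float
    whisker_high: float


def split_periods(rates: RateTable, design: PeriodDesign) -> tuple[RateTable, RateTable]:
    """Partition the year axis at the cutoff; both halves must be non-empty."""
    years = np.asarray(rates.years)
    pre_years = years[years <= design.cutoff_year]
    post_years = years[years > design.cutoff_year]
    if len(pre_years) == 0 or len(post_years) == 0:
        raise ValueError(
            f"cutoff {design.cutoff_year} leaves an empty period for year span "
            f"{years.min()}-{years.max()}"
        )
    frame = rates.rates
    return RateTable(frame[list(pre_years)]), RateTable(frame[list(post_years)])


def _summary(sector: str, period: str, values: np.ndarray) -> PeriodSummary:
    n = len(values)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    in_lo = values[values >= q1 - 1.5 * iqr]
    in_hi = values[values <= q3 + 1.5 * iqr]
    return PeriodSummary(
        sector=sector,
        period=period,
        n=n,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n > 1 else float("nan"),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        minimum=float(values.min()),
        maximum=float(values.max()),
        whisker_low=float(in_lo.min()),
        whisker_high=float(in_hi.max()),
    )


def summarize(rates: RateTable, design: PeriodDesign) -> list[PeriodSummary]:
    """Per-sector, per-period descriptive summaries.

    A sector with no observed year in one of the periods is excluded with a
    warning (it cannot be compared across periods).
    """
    pre, post = split_periods(rates, design)
    out: list[PeriodSummary] = []
    for sector in rates.sectors:
        series = {
            design.labels[0]: pre.sector_series(sector).to_numpy(),
            design.labels[1]: post.sector_series(sector).to_numpy(),
        }
        if any(len(v) == 0 for v in series.values()):
            logger.warning("sector %r has an empty period; excluded from summaries", sector)
            continue
        for period, values in series.items():
            out.append(_summary(sector, period, values))
    return out


def summary_frame(summaries: list[PeriodSummary]) -> pd.DataFrame:
    """Tabular export of summaries (one row per sector x period)."""
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])
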