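"""NPC ranking: combine yearly partial rankings of sectors into a global ranking.

Within each year the sectors are ranked by dispute rate (rank 1 = highest,
ties -> average rank), and each sector receives a score in (0, 1) that
decreases with its rank.  Scores are combined across the years of a period
with the Fisher-type combining function

    combined(sector) = -2 * sum_years log(1 - score)

and sectors are ordered by descending combined score (rank 1 = worst,
i.e. highest fraud pressure).

Two score transforms are available:

``rate`` (default)
    The dispute rate itself is the score.  Rates are already proportions
    in (0, 1), the combination is then additive in a quantity that is
    monotone in the rate, and after max-normalisation the combined values
    can be read on the rate scale.  On the ICQRF record this ordering
    coincides with the ordering of sectors by period mean rate.
``midrank``
    score = (k - rank + 0.5) / k with k the number of sectors present that
    year.  Purely rank-based, hence invariant under any strictly
    increasing within-year transformation of the rates.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import RateTable
from .descriptives import PeriodDesign, split_periods

logger = logging.getLogger(__name__)

TRANSFORMS = ("rate", "midrank")


@dataclasses.dataclass(frozen=True)
class RankMatrix:
    """Within-year ranks (1 = highest rate) and their (0, 1) scores."""

    ranks: pd.DataFrame
    scores: pd.DataFrame
    transform: str


@dataclasses.dataclass(frozen=True)
class GlobalRanking:
    """Combined per-period ranking.

    ``frame`` is indexed by sector with columns combined_score,
    global_rank (1 = highest fraud pressure; average ranks on exact score
    ties, flagged in ``tied``).  ``scale`` optionally carries the period's
    maximum sector mean rate, used to express scores on the rate scale.
    """

    frame: pd.DataFrame
    period: str = ""
    scale: float | None = None

    def rank_of(self, sector: str) -> float:
        return float(self.frame.at[sector, "global_rank"])

    @property
    def sectors(self) -> tuple[str, ...]:
        return tuple(self.frame.index)


def yearly_ranks(rates: RateTable, transform: str = "rate") -> RankMatrix:
    """Rank sectors within each year and attach normalized scores.

    Missing cells are ranked among the sectors present that year only, and
    midrank scores are normalised by the number present.  A year with all
    cells missing is skipped with a warning.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    frame = rates.rates
    if len(frame.index) < 2:
        raise ValueError("ranking needs at least two sectors")
    ranks = pd.DataFrame(np.nan, index=frame.index, columns=frame.columns)
    scores = pd.DataFrame(np.nan, index=frame.index, columns=frame.columns)
    for year in frame.columns:
        column = frame[year]
        present = column.dropna()
        if present.empty:
            logger.warning("year %s has no observed rates; skipped in ranking", year)
            continue
        k = len(present)
        r = rankdata(-present.to_numpy(), method="average")
        ranks.loc[present.index, year] = r
        if transform == "midrank":
            scores.loc[present.index, year] = (k - r + 0.5) / k
        else:
            # dispute rates are proportions; nudge an exact 1.0 inside (0, 1)
            scores.loc[present.index, year] = np.minimum(
                present.to_numpy(), np.nextafter(1.0, 0.0)
            )
    kept = ranks.columns[ranks.notna().any(axis=0)]
    return RankMatrix(ranks=ranks[kept], scores=scores[kept], transform=transform)


def combine_ranking(matrix: RankMatrix, period: str = "", scale: float | None = None) -> GlobalRanking:
    """Fisher-combine yearly scores into a global per-period ranking.

    Combined scores are additive over years, so combining the union of two
    year sets equals summing their separate combinations.
    """
    if matrix.scores.shape[1] == 0:
        raise ValueError("no ranked years to combine")
    combined = (-2.0 * np.log1p(-matrix.scores)).sum(axis=1, skipna=True)
    global_rank = pd.Series(
        rankdata(-combined.to_numpy(), method="average"), index=combined.index
    )
    tied = global_rank.duplicated(keep=False)
    frame = pd.DataFrame(
        {"combined_score": combined, "global_rank": global_rank, "tied": tied}
    )
    frame.index.name = "sector"
    frame = frame.sort_values("global_rank", kind="stable")
    return GlobalRanking(frame=frame, period=period, scale=scale)


def period_rankings(
    rates: RateTable, design: PeriodDesign, transform: str = "rate"
) -> tuple[GlobalRanking, GlobalRanking]:
    """Global rankings for the two periods of a cutoff design.

    Each ranking records the period's maximum sector mean rate as its
    display scale, so bar-chart values can be expressed in rate units.
    """
    halves = split_periods(rates, design)
    out = []
    for table, label in zip(halves, design.labels):
        scale = float(table.rates.mean(axis=1, skipna=True).max())
        out.append(combine_ranking(yearly_ranks(table, transform), period=label, scale=scale))
    return out[0], out[1]


def ranking_report(pre: GlobalRanking, post: GlobalRanking) -> pd.DataFrame:
    """Rank-change table plus bar-chart values on the rate scale.

    Bar values are the combined scores max-normalised to the period's
    maximum sector mean rate (when a scale is recorded), so the two
    horizontal bar charts read in the same units as the dispute rates.
    """
    if set(pre.sectors) != set(post.sectors):
        raise ValueError("pre and post rankings cover different sector sets")
    sectors = sorted(pre.sectors)

    def bars(ranking: GlobalRanking) -> pd.Series:
        s = ranking.frame["combined_score"]
        if ranking.scale is None or s.max() == 0:
            return s
        return s / s.max() * ranking.scale

    pre_bars, post_bars = bars(pre), bars(post)
    frame = pd.DataFrame(
        {
            "pre_rank": [pre.rank_of(s) for s in sectors],
            "post_rank": [post.rank_of(s) for s in sectors],
            "pre_bar": [float(pre_bars[s]) for s in sectors],
            "post_bar": [float(post_bars[s]) for s in sectors],
        },
        index=pd.Index(sectors, name="sector"),
    )
    frame["delta"] = frame["post_rank"] - frame["pre_rank"]
    return frame
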