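"""Figure generation: period boxplots and ranking bar charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .data_io import RateTable
from .descriptives import PeriodDesign, split_periods
from .npc_ranking import GlobalRanking, ranking_report


def boxplot_figure(rates: RateTable, design: PeriodDesign, path: str | Path) -> None:
    """One boxplot panel per sector, two boxes each (period 1 vs period 2).

    Whiskers follow the Tukey 1.5 x IQR convention (a display default; the
    summaries exported alongside carry the fence values explicitly).
    """
    pre, post = split_periods(rates, design)
    sectors = rates.sectors
    ncols = 3
    nrows = -(-len(sectors) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
    for ax, sector in zip(axes.flat, sectors):
        data = [pre.sector_series(sector).to_numpy(), post.sector_series(sector).to_numpy()]
        ax.boxplot(data, tick_labels=list(design.labels), whis=1.5)
        ax.set_title(sector, fontsize=9)
        ax.set_ylabel("dispute rate", fontsize=8)
    for ax in axes.flat[len(sectors):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ranking_bar_figure(pre: GlobalRanking, post: GlobalRanking, path: str | Path) -> None:
    """Horizontal bar charts of the two global rankings, bars on the rate scale."""
    report = ranking_report(pre, post)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2), sharex=True)
    for ax, (ranking, column) in zip(
        axes, [(pre, "pre_bar"), (post, "post_bar")]
    ):
        ordered = report.sort_values(column)
        ax.barh(ordered.index, ordered[column], color="#4878a8")
        ax.set_title(f"global ranking, {ranking.period or column.split('_')[0]}")
        ax.set_xlabel("combined score (rate units)")
        ax.tick_params(labelsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
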