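"""Nonparametric combination (NPC) permutation tests for two-period rate changes.

The global null states that every sector's dispute-rate distribution is the
same in the two periods; the alternative is that at least one sector
changed.  Each sector contributes a partial two-sample permutation test
with statistic |mean(period 1) - mean(period 2)|, two-sided by
construction.  Dependence between sectors is preserved by permuting whole
*years*: one reassignment of year labels to periods drives every sector's
partial statistic simultaneously.

The combined test follows the standard two-step NPC recipe: each
permutation's partial statistics are converted to permutation-wise
significance levels against the pooled permutation distribution, combined
with a combining function (Fisher -2*sum(log p), Liptak sum(Phi^-1(1-p)),
or Tippett max(1-p)), and the observed combined value is referred to the
combined permutation distribution.

Splits of the year axis are enumerated exhaustively when their number
C(n1+n2, n1) is small enough; otherwise Conditional Monte Carlo (CMC)
sampling is used with the +1/(B+1) estimator, which keeps every p-value
strictly positive.  Exhaustive p-values are exact rationals
(count >= observed) / (number of splits) and do not depend on any seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from collections.abc import Callable, Sequence
from math import comb

import numpy as np
from scipy.special import ndtri

from .data_io import RateTable
from .descriptives import PeriodDesign

logger = logging.getLogger(__name__)

COMBINERS = ("fisher", "liptak", "tippett")

#: Default seed recorded in CMC-mode outputs (the hygiene-package date).
DEFAULT_SEED = 20040101


@dataclasses.dataclass(frozen=True)
class NPCConfig:
    """Settings for the NPC global test.

    ``max_exhaustive`` bounds the number of splits enumerated exactly
    (C(24, 8) = 735,471 on the full 1997-2020 design qualifies under the
    default of 10^6); larger spaces fall back to CMC with ``n_monte_carlo``
    random splits.  ``bonferroni`` optionally adds multiplicity-adjusted
    partial p-values; raw partial p-values are always reported.
    """

    combiner: str = "fisher"
    max_exhaustive: int = 1_000_000
    n_monte_carlo: int = 10_000
    seed: int = DEFAULT_SEED
    alpha: float = 0.05
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}; choose from {COMBINERS}")
        if self.n_monte_carlo < 100:
            raise ValueError("n_monte_carlo must be at least 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclasses.dataclass(frozen=True)
class PartialTestResult:
    """One sector's two-period permutation test.

    ``mean_difference`` is signed (period 1 minus period 2) so reports can
    state the direction of the change; ``statistic`` is its absolute value.
    ``seed`` is None in exhaustive mode, where the p-value is exact.
    """

    sector: str
    statistic: float
    p_value: float
    mode: str
    n_permutations: int
    mean_difference: float
    seed: int | None = None
    p_adjusted: float | None = None


@dataclasses.dataclass(frozen=True)
class NPCGlobalResult:
    partials: tuple[PartialTestResult, ...]
    combiner: str
    combined_statistic: float
    global_p_value: float
    alpha: float
    mode: str
    n_permutations: int
    seed: int | None = None

    @property
    def rejected(self) -> bool:
        return self.global_p_value < self.alpha


# ---------------------------------------------------------------------------
# partial statistic and split machinery
# ---------------------------------------------------------------------------


def partial_statistic(series1: Sequence[float], series2: Sequence[float]) -> float:
    """Absolute difference of period means; symmetric in its arguments."""
    a = np.asarray(series1, dtype=float)
    b = np.asarray(series2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both series must be non-empty")
    return float(abs(a.mean() - b.mean()))


def _exhaustive_splits(n: int, n1: int) -> np.ndarray:
    """All C(n, n1) index subsets assigning positions to group 1.

    Row 0 is the identity split (0, ..., n1-1): with observations laid out
    period 1 first, it reproduces the observed assignment.
    """
    return np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
        count=comb(n, n1) * n1,
    ).reshape(-1, n1)


def _cmc_splits(n: int, n1: int, n_monte_carlo: int, seed: int) -> np.ndarray:
    """The identity split plus ``n_monte_carlo`` uniform random splits."""
    rng = np.random.default_rng(seed)
    random_part = np.argsort(rng.random((n_monte_carlo, n)), axis=1)[:, :n1]
    return np.vstack([np.arange(n1, dtype=np.intp), random_part.astype(np.intp)])


#: Statistics are rounded at this decimal before tie comparison, so splits
#: tied in exact arithmetic (e.g. complementary splits when n1 = n2) stay
#: tied despite summation-order noise; see the methods documentation.
_TIE_DECIMALS = 12


def _split_statistics(pooled: np.ndarray, splits: np.ndarray) -> np.ndarray:
    """|group-1 mean - group-2 mean| for every split, vectorised."""
    n = pooled.size
    n1 = splits.shape[1]
    n2 = n - n1
    total = pooled.sum()
    s1 = pooled[splits].sum(axis=1)
    return np.round(np.abs(s1 / n1 - (total - s1) / n2), _TIE_DECIMALS)


def _count_ge(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """For each reference value, how many of ``values`` are >= it (ties count)."""
    ordered = np.sort(values)
    return values.size - np.searchsorted(ordered, reference, side="left")


def permutation_pvalue(
    series1: Sequence[float],
    series2: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    max_exhaustive: int = 1_000_000,
    n_monte_carlo: int = 10_000,
    seed: int = DEFAULT_SEED,
    sector: str = "",
) -> PartialTestResult:
    """Two-sample permutation p-value for a single sector's series.

    The null distribution reassigns the pooled n1+n2 observations to groups
    of the original sizes.  All C(n1+n2, n1) splits are enumerated when that
    count is <= ``max_exhaustive`` (p-value exact, seed-free); otherwise CMC
    sampling with p = (1 + #{random splits >= observed}) / (1 + B).

    A custom ``statistic`` callable (group1, group2) -> float may replace
    the default absolute mean difference; ties with the observed value
    count towards rejection (conservative).
    """
    a = np.asarray(series1, dtype=float)
    b = np.asarray(series2, dtype=float)
    if a.size + b.size < 2:
        raise ValueError("need at least two observations in total")
    if a.size == 0 or b.size == 0:
        raise ValueError("both series must be non-empty")
    if n_monte_carlo < 100:
        raise ValueError("n_monte_carlo must be at least 100")
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    n_splits = comb(n, n1)
    exhaustive = n_splits <= max_exhaustive
    if exhaustive:
        splits = _exhaustive_splits(n, n1)
    else:
        splits = _cmc_splits(n, n1, n_monte_carlo, seed)
    if statistic is None:
        stats = _split_statistics(pooled, splits)
        observed = float(stats[0])
    else:
        mask = np.zeros(n, dtype=bool)
        stats = np.empty(len(splits))
        for i, split in enumerate(splits):
            mask[:] = False
            mask[split] = True
            stats[i] = statistic(pooled[mask], pooled[~mask])
        stats = np.round(stats, _TIE_DECIMALS)
        observed = float(stats[0])
    p = float((stats >= observed).sum() / stats.size)
    return PartialTestResult(
        sector=sector,
        statistic=observed,
        p_value=p,
        mode="exhaustive" if exhaustive else "conditional-monte-carlo",
        n_permutations=int(stats.size if exhaustive else n_monte_carlo),
        mean_difference=float(a.mean() - b.mean()),
        seed=None if exhaustive else seed,
    )


# ---------------------------------------------------------------------------
# combining functions
# ---------------------------------------------------------------------------


def combine(partial_pvalues: Sequence[float], function_name: str = "fisher") -> float:
    """Combine partial p-values into a single statistic.

    Fisher and Liptak are strictly decreasing in every partial p-value;
    Tippett is non-increasing.  p-values must lie in (0, 1]; a zero would
    send Fisher to infinity and is rejected (the CMC +1 correction makes
    zero unreachable in practice).
    """
    p = np.asarray(partial_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one partial p-value")
    if (p <= 0.0).any() or (p > 1.0).any():
        raise ValueError(f"partial p-values must lie in (0, 1]; got {p}")
    if function_name == "fisher":
        return float(-2.0 * np.log(p).sum())
    if function_name == "liptak":
        return float(ndtri(1.0 - p).sum())
    if function_name == "tippett":
        return float((1.0 - p).max())
    raise ValueError(f"unknown combiner {function_name!r}; choose from {COMBINERS}")


def _combine_matrix(levels: np.ndarray, function_name: str) -> np.ndarray:
    """Row-wise combination of a (splits x sectors) matrix of p-levels.

    For Liptak the level 1 attained by each sector's minimum statistic is
    pulled just inside (0, 1) to keep Phi^-1 finite; order is unaffected.
    """
    if function_name == "fisher":
        return -2.0 * np.log(levels).sum(axis=1)
    if function_name == "liptak":
        clipped = np.minimum(levels, 1.0 - 0.5 / levels.shape[0])
        return ndtri(1.0 - clipped).sum(axis=1)
    if function_name == "tippett":
        return (1.0 - levels).max(axis=1)
    raise ValueError(f"unknown combiner {function_name!r}; choose from {COMBINERS}")


# ---------------------------------------------------------------------------
# global test
# ---------------------------------------------------------------------------


def npc_global_test(
    rates: RateTable,
    design: PeriodDesign,
    config: NPCConfig = NPCConfig(),
) -> NPCGlobalResult:
    """NPC global test of "no sector changed between the periods".

    The permutation unit is the year: each split reassigns year labels to
    the two periods once and applies that same reassignment to every
    sector's series, preserving cross-sector dependence.  Years containing
    a missing cell in any sector are dropped (with a warning) so that every
    permutation acts on complete multivariate observations.
    """
    frame = rates.rates
    complete = frame.columns[frame.notna().all(axis=0)]
    dropped = [int(y) for y in frame.columns if y not in complete]
    if dropped:
        logger.warning("dropping %d incomplete year(s) from NPC test: %s", len(dropped), dropped)
    frame = frame[complete]
    years = np.array([int(y) for y in frame.columns])
    pre_mask = years <= design.cutoff_year
    n1, n2 = int(pre_mask.sum()), int((~pre_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"cutoff {design.cutoff_year} leaves an empty period")
    # lay out period-1 years first so the identity split is row 0
    matrix = np.hstack(
        [frame.loc[:, frame.columns[pre_mask]].to_numpy(),
         frame.loc[:, frame.columns[~pre_mask]].to_numpy()]
    )
    sectors = list(frame.index)
    n = n1 + n2
    n_splits = comb(n, n1)
    exhaustive = n_splits <= config.max_exhaustive
    if exhaustive:
        splits = _exhaustive_splits(n, n1)
    else:
        splits = _cmc_splits(n, n1, config.n_monte_carlo, config.seed)
    n_rows = len(splits)

    stats = np.empty((n_rows, len(sectors)))
    for j in range(len(sectors)):
        stats[:, j] = _split_statistics(matrix[j], splits)

    # permutation-wise partial significance levels from the pooled distribution
    levels = np.empty_like(stats)
    for j in range(len(sectors)):
        levels[:, j] = _count_ge(stats[:, j], stats[:, j]) / n_rows
    combined = np.round(_combine_matrix(levels, config.combiner), 10)
    global_p = float((combined >= combined[0]).sum() / n_rows)

    mode = "exhaustive" if exhaustive else "conditional-monte-carlo"
    seed = None if exhaustive else config.seed
    partials = []
    for j, sector in enumerate(sectors):
        p = float(levels[0, j])
        partials.append(
            PartialTestResult(
                sector=sector,
                statistic=float(stats[0, j]),
                p_value=p,
                mode=mode,
                n_permutations=int(n_rows if exhaustive else config.n_monte_carlo),
                mean_difference=float(
                    matrix[j, :n1].mean() - matrix[j, n1:].mean()
                ),
                seed=seed,
                p_adjusted=min(1.0, p * len(sectors)) if config.bonferroni else None,
            )
        )
    return NPCGlobalResult(
        partials=tuple(partials),
        combiner=config.combiner,
        combined_statistic=float(combined[0]),
        global_p_value=global_p,
        alpha=config.alpha,
        mode=mode,
        n_permutations=int(n_rows if exhaustive else config.n_monte_carlo),
        seed=seed,
    )
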