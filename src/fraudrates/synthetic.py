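"""Synthetic inspection-count panels with the structure the analysis assumes.

Each sector has a baseline dispute probability in period 1 and an additive
shift in period 2; the irregularity count of a sector-year cell is drawn
binomially given the cell's inspection count.  Binomial noise on counts
(rather than Gaussian noise on rates) reproduces the variance-mean
coupling visible in low-rate sectors: a rate near 0.05 simply cannot
fluctuate as widely as one near 0.4 at equal inspection effort.

Inspection counts per cell are either a fixed integer or drawn
lognormally around a per-sector mean (multiplicative spread ``sigma``,
mean-preserving), mimicking the year-to-year variation of real inspection
effort, whose true per-year values are unpublished.

One root seed drives everything; replicate studies derive per-replicate
seeds through a counter-based spawn scheme so each replicate is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import yaml

from .data_io import CANONICAL_SECTORS, InspectionRecord, InspectionTable, compute_rates
from .descriptives import PeriodDesign
from .npc_test import NPCConfig, npc_global_test


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of the synthetic surveillance panel.

    Defaults mirror the ICQRF study design: 9 sectors observed 1997-2020
    with the period cutoff at 2004 (8 + 16 years).  ``baseline_rates`` are
    period-1 dispute probabilities, ``effects`` the additive period-2
    shifts; both per sector, with baseline and baseline+effect in [0, 1].
    ``inspections`` is a fixed per-cell count or a per-sector mean, spread
    lognormally with multiplicative sigma ``overdispersion`` (0 = exact).
    """

    baseline_rates: tuple[float, ...]
    effects: tuple[float, ...]
    sectors: tuple[str, ...] = CANONICAL_SECTORS
    start_year: int = 1997
    end_year: int = 2020
    cutoff_year: int = 2004
    inspections: int | tuple[float, ...] = 1000
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.sectors)
        if len(self.baseline_rates) != k or len(self.effects) != k:
            raise ValueError("baseline_rates and effects must have one entry per sector")
        for s, b, e in zip(self.sectors, self.baseline_rates, self.effects):
            if not 0.0 <= b <= 1.0 or not 0.0 <= b + e <= 1.0:
                raise ValueError(
                    f"sector {s!r}: baseline {b} and baseline+effect {b + e} "
                    "must lie in [0, 1]"
                )
        means = self._inspection_means()
        if len(means) != k:
            raise ValueError("per-sector inspections must have one entry per sector")
        if any(m < 1 for m in means):
            raise ValueError("inspections per cell must be >= 1")
        if not self.start_year <= self.cutoff_year < self.end_year:
            raise ValueError("cutoff must leave both periods non-empty")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")

    def _inspection_means(self) -> tuple[float, ...]:
        if isinstance(self.inspections, (int, float)):
            return (float(self.inspections),) * len(self.sectors)
        return tuple(float(m) for m in self.inspections)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.end_year + 1))

    @property
    def design(self) -> PeriodDesign:
        return PeriodDesign(cutoff_year=self.cutoff_year)


def fixture_like_config(seed: int = 0, overdispersion: float = 0.25) -> SyntheticConfig:
    """A configuration resembling the ICQRF record.

    Baselines are each sector's pre-2004 fixture mean rate, effects the
    post-minus-pre mean differences, and inspection means each sector's
    whole-period total spread evenly over the 24 years.
    """
    from .data_io import builtin_fixture, sector_and_grand_totals
    from .descriptives import split_periods

    totals, rates = builtin_fixture()
    per_sector, _ = sector_and_grand_totals(totals)
    design = PeriodDesign(cutoff_year=2004)
    pre, post = split_periods(rates, design)
    sectors = rates.sectors
    baselines = tuple(float(pre.sector_series(s).mean()) for s in sectors)
    post_means = tuple(float(post.sector_series(s).mean()) for s in sectors)
    n_years = len(rates.years)
    means = tuple(float(per_sector.at[s, "inspections"]) / n_years for s in sectors)
    return SyntheticConfig(
        baseline_rates=baselines,
        effects=tuple(p - b for b, p in zip(baselines, post_means)),
        sectors=sectors,
        inspections=means,
        overdispersion=overdispersion,
        seed=seed,
    )


def generate(config: SyntheticConfig, rng: np.random.Generator | None = None) -> InspectionTable:
    """Draw one synthetic inspection panel; identical seed -> identical table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    means = config._inspection_means()
    records = []
    for j, sector in enumerate(config.sectors):
        for year in config.years:
            mean = means[j]
            if config.overdispersion > 0:
                # mean-preserving lognormal: E[exp(N(-s^2/2, s))] = 1
                factor = rng.lognormal(-config.overdispersion**2 / 2, config.overdispersion)
                n_insp = max(1, int(round(mean * factor)))
            else:
                n_insp = max(1, int(round(mean)))
            p = config.baseline_rates[j]
            if year > config.cutoff_year:
                p = p + config.effects[j]
            n_irr = int(rng.binomial(n_insp, p))
            records.append(InspectionRecord(sector, year, n_insp, n_irr))
    return InspectionTable(records, year_range=(config.start_year, config.end_year))


# ---------------------------------------------------------------------------
# config (de)serialisation
# ---------------------------------------------------------------------------


def config_to_file(config: SyntheticConfig, path: str | Path) -> None:
    """Write a config as YAML (or JSON if the suffix is .json)."""
    payload = dataclasses.asdict(config)
    payload["sectors"] = list(payload["sectors"])
    payload["baseline_rates"] = list(payload["baseline_rates"])
    payload["effects"] = list(payload["effects"])
    if isinstance(payload["inspections"], tuple):
        payload["inspections"] = list(payload["inspections"])
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))


def config_from_file(path: str | Path) -> SyntheticConfig:
    path = Path(path)
    text = path.read_text()
    payload: Mapping = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    payload = dict(payload)
    for key in ("sectors", "baseline_rates", "effects"):
        if key in payload:
            payload[key] = tuple(payload[key])
    if isinstance(payload.get("inspections"), Sequence) and not isinstance(
        payload.get("inspections"), (str, bytes)
    ):
        payload["inspections"] = tuple(payload["inspections"])
    return SyntheticConfig(**payload)


# ---------------------------------------------------------------------------
# operating characteristics
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OperatingCharacteristics:
    """Size/power and effect-recovery summary of a replicated simulation."""

    alpha: float
    n_replicates: int
    global_rejection_rate: float
    sector_rejection_rates: Mapping[str, float]
    effect_mae: float


def replicate_seed(root_seed: int, replicate: int) -> np.random.SeedSequence:
    """Counter-based per-replicate seed stream."""
    return np.random.SeedSequence(entropy=root_seed, spawn_key=(replicate,))


def estimate_operating_characteristics(
    config: SyntheticConfig,
    analysis: NPCConfig = NPCConfig(max_exhaustive=0, n_monte_carlo=500),
    n_replicates: int = 1000,
    alpha: float | None = None,
) -> OperatingCharacteristics:
    """Monte-Carlo size/power of the NPC test under a known truth.

    Each replicate draws a panel, computes rates and runs the global NPC
    test; rejection uses ``p < alpha`` on the global and partial p-values.
    ``effect_mae`` is the mean absolute error of the naive effect estimate
    (period-2 mean rate minus period-1 mean rate) against the configured
    effects, averaged over sectors and replicates.
    """
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates for stable rates")
    if alpha is None:
        alpha = analysis.alpha
    design = config.design
    pre_years = [y for y in config.years if y <= config.cutoff_year]
    n_global_rej = 0
    n_partial_rej = {s: 0 for s in config.sectors}
    abs_err_sum = 0.0
    for rep in range(n_replicates):
        ss = replicate_seed(config.seed, rep)
        gen_seed, test_seed = ss.generate_state(2) % (2**31)
        table = generate(config, rng=np.random.default_rng(int(gen_seed)))
        rates = compute_rates(table)
        rep_analysis = dataclasses.replace(analysis, seed=int(test_seed))
        result = npc_global_test(rates, design, rep_analysis)
        if result.global_p_value < alpha:
            n_global_rej += 1
        for partial in result.partials:
            if partial.p_value < alpha:
                n_partial_rej[partial.sector] += 1
        frame = rates.rates
        pre_mean = frame[pre_years].mean(axis=1)
        post_mean = frame[[y for y in config.years if y > config.cutoff_year]].mean(axis=1)
        estimated = (post_mean - pre_mean).reindex(list(config.sectors)).to_numpy()
        abs_err_sum += float(np.abs(estimated - np.asarray(config.effects)).mean())
    return OperatingCharacteristics(
        alpha=alpha,
        n_replicates=n_replicates,
        global_rejection_rate=n_global_rej / n_replicates,
        sector_rejection_rates={s: c / n_replicates for s, c in n_partial_rej.items()},
        effect_mae=abs_err_sum / n_replicates,
    )
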