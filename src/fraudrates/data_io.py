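"""Reading, writing and validation of inspection-count and dispute-rate tables.

The two central containers are :class:`InspectionTable` (sector x year counts
of inspections and of irregularities found) and :class:`RateTable` (sector x
year dispute rates, i.e. irregularities / inspections, a proportion in
[0, 1]).  Both wrap a :class:`pandas.DataFrame` and enforce their invariants
at construction time, so every downstream stage can assume a clean table.

A packaged fixture carries the Italian ICQRF inspection record for
1997-2020: the nine per-sector whole-period totals and the 9 x 24 matrix of
yearly dispute rates (see :func:`builtin_fixture`).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping
from importlib import resources
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PathLike = Union[str, Path, IO[str]]

#: Canonical vocabulary of the nine ICQRF agri-food sectors.
CANONICAL_SECTORS: tuple[str, ...] = (
    "wine",
    "milk and dairy products",
    "oils and fats",
    "feed and supplements",
    "eggs",
    "honey",
    "sowing seeds",
    "vegetable preserves",
    "meat",
)

_DEFAULT_DIALECT: Mapping[str, str] = {
    "sector": "sector",
    "year": "year",
    "inspections": "inspections",
    "irregularities": "irregularities",
    "rate": "rate",
}


class ValidationError(ValueError):
    """A table violates one of its declared invariants."""


class ConfigurationError(ValueError):
    """The reader configuration (column map, orientation) cannot be applied."""


def normalize_sector(label: str) -> str:
    """Trim and lowercase a sector label (aliases are case-insensitive)."""
    return " ".join(str(label).strip().lower().split())


@dataclasses.dataclass(frozen=True)
class InspectionRecord:
    """One sector-year cell of the inspection record.

    Invariants: counts are non-negative integers and the number of
    irregularities can never exceed the number of inspections that could
    have produced them.
    """

    sector: str
    year: int
    inspections: int
    irregularities: int

    def __post_init__(self) -> None:
        if self.inspections < 0 or self.irregularities < 0:
            raise ValidationError(
                f"negative count for ({self.sector!r}, {self.year}): "
                f"inspections={self.inspections}, irregularities={self.irregularities}"
            )
        if self.irregularities > self.inspections:
            raise ValidationError(
                f"irregularities ({self.irregularities}) exceed inspections "
                f"({self.inspections}) for ({self.sector!r}, {self.year})"
            )


class InspectionTable:
    """A validated collection of :class:`InspectionRecord`.

    At most one record per (sector, year); an optional declared year range
    is enforced on every record.
    """

    def __init__(
        self,
        records: Iterable[InspectionRecord],
        year_range: tuple[int, int] | None = None,
    ) -> None:
        records = tuple(records)
        seen: set[tuple[str, int]] = set()
        for rec in records:
            key = (rec.sector, rec.year)
            if key in seen:
                raise ValidationError(f"duplicate record for {key}")
            seen.add(key)
            if year_range is not None and not (year_range[0] <= rec.year <= year_range[1]):
                raise ValidationError(
                    f"year {rec.year} outside declared range {year_range} "
                    f"for sector {rec.sector!r}"
                )
        self._records = records
        self.year_range = year_range

    @property
    def records(self) -> tuple[InspectionRecord, ...]:
        return self._records

    @property
    def sectors(self) -> tuple[str, ...]:
        return tuple(sorted({r.sector for r in self._records}))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({r.year for r in self._records}))

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns sector, year, inspections, irregularities."""
        frame = pd.DataFrame(
            [dataclasses.asdict(r) for r in self._records],
            columns=["sector", "year", "inspections", "irregularities"],
        )
        return frame.sort_values(["sector", "year"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self._records)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"InspectionTable({len(self._records)} records, "
            f"{len(self.sectors)} sectors, {len(self.years)} years)"
        )


class RateTable:
    """Sector x year matrix of dispute rates.

    Values are proportions in [0, 1]; absent cells are held as NaN and are
    excluded (with a logged warning) from downstream statistics.  Both axes
    are duplicate-free and sorted.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.size == 0:
            raise ValidationError("no data: rate table is empty")
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sector rows: {dups}")
        if frame.columns.has_duplicates:
            dups = frame.columns[frame.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate year columns: {dups}")
        frame = frame.copy()
        frame.index = pd.Index([normalize_sector(s) for s in frame.index], name="sector")
        if frame.index.has_duplicates:
            raise ValidationError("sector labels collide after normalization")
        frame.columns = pd.Index([int(y) for y in frame.columns], name="year")
        frame = frame.sort_index().sort_index(axis=1).astype(float)
        values = frame.to_numpy()
        bad = ~np.isnan(values) & ((values < 0.0) | (values > 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"rate {values[i, j]} outside [0, 1] for "
                f"({frame.index[i]!r}, {frame.columns[j]})"
            )
        if np.isnan(values).all():
            raise ValidationError("no data: all cells missing")
        self._frame = frame

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_cells(cls, cells: Iterable[tuple[str, int, float]]) -> "RateTable":
        """Build from (sector, year, rate) triples; unlisted cells are missing."""
        cells = list(cells)
        if not cells:
            raise ValidationError("no data: empty cell list")
        seen: set[tuple[str, int]] = set()
        for sector, year, _ in cells:
            key = (normalize_sector(sector), int(year))
            if key in seen:
                raise ValidationError(f"duplicate cell for {key}")
            seen.add(key)
        frame = pd.DataFrame(
            [(normalize_sector(s), int(y), float(r)) for s, y, r in cells],
            columns=["sector", "year", "rate"],
        ).pivot(index="sector", columns="year", values="rate")
        return cls(frame)

    # -- accessors ------------------------------------------------------------

    @property
    def rates(self) -> pd.DataFrame:
        """The underlying sector x year matrix (a defensive copy)."""
        return self._frame.copy()

    @property
    def sectors(self) -> tuple[str, ...]:
        return tuple(self._frame.index)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self._frame.columns)

    def rate(self, sector: str, year: int) -> float:
        return float(self._frame.at[normalize_sector(sector), int(year)])

    def sector_series(self, sector: str) -> pd.Series:
        """Yearly rates for one sector, missing cells dropped."""
        return self._frame.loc[normalize_sector(sector)].dropna()

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self._frame.isna()

    @property
    def n_missing(self) -> int:
        return int(self._frame.isna().to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RateTable) and self._frame.equals(other._frame)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"RateTable({len(self.sectors)} sectors x {len(self.years)} years, "
            f"{self.n_missing} missing)"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _resolve_columns(
    frame: pd.DataFrame, dialect: Mapping[str, str] | None, roles: Iterable[str]
) -> dict[str, str]:
    """Map semantic roles onto actual column names, case-insensitively."""
    mapping = dict(_DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    lower = {str(c).strip().lower(): c for c in frame.columns}
    resolved = {}
    for role in roles:
        wanted = mapping[role].strip().lower()
        if wanted not in lower:
            raise ConfigurationError(
                f"column for {role!r} (expected {mapping[role]!r}) not found; "
                f"available: {list(frame.columns)}"
            )
        resolved[role] = lower[wanted]
    return resolved


def _strip_thousands(series: pd.Series) -> pd.Series:
    return series.astype(str).str.replace(",", "", regex=False).str.strip()


def load_inspection_table(
    source: PathLike,
    dialect: Mapping[str, str] | None = None,
    year_range: tuple[int, int] | None = None,
) -> InspectionTable:
    """Read a long-format CSV of inspection and irregularity counts.

    ``dialect`` maps the roles sector/year/inspections/irregularities to the
    file's column names.  Thousands separators in count columns are
    stripped.  Rows violating the count invariants raise
    :class:`ValidationError` naming the offending (sector, year) rather than
    being silently dropped.
    """
    frame = pd.read_csv(source, dtype=str)
    cols = _resolve_columns(frame, dialect, ("sector", "year", "inspections", "irregularities"))
    records = []
    for _, row in frame.iterrows():
        sector = normalize_sector(row[cols["sector"]])
        year = int(str(row[cols["year"]]).strip())
        inspections = int(_strip_thousands(pd.Series([row[cols["inspections"]]]))[0])
        irregularities = int(_strip_thousands(pd.Series([row[cols["irregularities"]]]))[0])
        records.append(InspectionRecord(sector, year, inspections, irregularities))
    return InspectionTable(records, year_range=year_range)


def load_rate_table(source: PathLike, orientation: str = "long") -> RateTable:
    """Read a dispute-rate CSV in ``long`` (sector,year,rate) or ``wide``
    (sector rows x year columns) orientation.

    Equivalent content in either orientation yields an identical table.
    """
    if orientation == "long":
        frame = pd.read_csv(source)
        cols = _resolve_columns(frame, None, ("sector", "year", "rate"))
        cells = [
            (str(row[cols["sector"]]), int(row[cols["year"]]), float(row[cols["rate"]]))
            for _, row in frame.iterrows()
        ]
        return RateTable.from_cells(cells)
    if orientation == "wide":
        frame = pd.read_csv(source, index_col=0)
        if frame.size == 0:
            raise ValidationError("no data: rate table is empty")
        return RateTable(frame)
    raise ConfigurationError(f"unknown orientation {orientation!r} (use 'long' or 'wide')")


def write_rate_table(table: RateTable, dest: PathLike, orientation: str = "long") -> None:
    """Write a rate table as CSV; floats use shortest round-tripping decimals."""
    frame = table.rates
    if orientation == "wide":
        out = frame.copy()
        out.index.name = "sector"
        out.to_csv(dest, float_format=None)
        return
    if orientation == "long":
        long = frame.stack().rename("rate").reset_index()
        long.columns = ["sector", "year", "rate"]
        long.to_csv(dest, index=False)
        return
    raise ConfigurationError(f"unknown orientation {orientation!r} (use 'long' or 'wide')")


def write_inspection_table(table: InspectionTable, dest: PathLike) -> None:
    table.to_frame().to_csv(dest, index=False)


# ---------------------------------------------------------------------------
# packaged ICQRF record
# ---------------------------------------------------------------------------


def builtin_fixture() -> tuple[InspectionTable, RateTable]:
    """The embedded ICQRF 1997-2020 record.

    Returns the nine per-sector whole-period totals of inspections and
    irregularities (records keyed to the span start year 1997, since no
    per-year count breakdown is published) and the 9 x 24 matrix of yearly
    dispute rates.  Identical across calls.
    """
    pkg = resources.files("fraudrates") / "data"
    with resources.as_file(pkg / "icqrf_sector_totals.csv") as path:
        frame = pd.read_csv(path)
        records = [
            InspectionRecord(normalize_sector(r["sector"]), 1997, int(r["inspections"]), int(r["irregularities"]))
            for _, r in frame.iterrows()
        ]
        totals = InspectionTable(records, year_range=(1997, 1997))
    with resources.as_file(pkg / "icqrf_dispute_rates.csv") as path:
        rates = load_rate_table(path, orientation="wide")
    return totals, rates


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def compute_rates(table: InspectionTable) -> RateTable:
    """Dispute rates: irregularities / inspections per cell, exact quotient.

    Cells with zero inspections carry no rate information and are marked
    missing (their irregularity count is necessarily zero by the record
    invariant); a warning is logged.
    """
    cells = []
    n_zero = 0
    for rec in table.records:
        if rec.inspections == 0:
            n_zero += 1
            cells.append((rec.sector, rec.year, float("nan")))
        else:
            cells.append((rec.sector, rec.year, rec.irregularities / rec.inspections))
    if n_zero:
        logger.warning("%d cell(s) with zero inspections marked missing", n_zero)
    if n_zero == len(cells):
        raise ValidationError("no data: no cell has a positive inspection count")
    return RateTable.from_cells(cells)


def sector_and_grand_totals(
    table: InspectionTable,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Per-sector and overall sums of inspections and irregularities.

    Sums are exact integer arithmetic (Python ints, no float accumulation).
    An empty table yields an empty frame and (0, 0).
    """
    per: dict[str, list[int]] = {}
    for rec in table.records:
        acc = per.setdefault(rec.sector, [0, 0])
        acc[0] += rec.inspections
        acc[1] += rec.irregularities
    frame = pd.DataFrame.from_dict(
        per, orient="index", columns=["inspections", "irregularities"]
    ).sort_index()
    frame.index.name = "sector"
    grand = (int(frame["inspections"].sum()) if len(frame) else 0,
             int(frame["irregularities"].sum()) if len(frame) else 0)
    return frame, grand
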