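"""Reading, validation, fixture integrity and exact-arithmetic checks."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fraudrates import (
    ConfigurationError,
    InspectionRecord,
    InspectionTable,
    RateTable,
    ValidationError,
    builtin_fixture,
    compute_rates,
    load_inspection_table,
    load_rate_table,
    sector_and_grand_totals,
    write_rate_table,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLoadInspectionTable:
    def test_basic_two_row_csv(self, tmp_path):
        path = _write(
            tmp_path,
            "counts.csv",
            "sector,year,inspections,irregularities\nwine,2000,100,25\nhoney,2000,50,5\n",
        )
        table = load_inspection_table(path)
        assert len(table) == 2
        assert table.sectors == ("honey", "wine")
        assert table.years == (2000,)

    def test_irregularities_exceeding_inspections_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "bad.csv",
            "sector,year,inspections,irregularities\nwine,2000,5,10\n",
        )
        with pytest.raises(ValidationError, match="wine.*2000"):
            load_inspection_table(path)

    def test_missing_column_is_a_configuration_error(self, tmp_path):
        path = _write(tmp_path, "bad.csv", "sector,year,count\nwine,2000,5\n")
        with pytest.raises(ConfigurationError, match="inspections"):
            load_inspection_table(path)

    def test_dialect_maps_and_thousands_separators(self, tmp_path):
        path = _write(
            tmp_path,
            "alias.csv",
            'Category,YEAR,Checks,Faults\n  Wine ,2000,"159,187","44,836"\n',
        )
        table = load_inspection_table(
            path,
            dialect={"sector": "Category", "inspections": "Checks", "irregularities": "Faults"},
        )
        rec = table.records[0]
        assert rec == InspectionRecord("wine", 2000, 159187, 44836)

    def test_duplicate_cell_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "dup.csv",
            "sector,year,inspections,irregularities\nwine,2000,10,1\nwine,2000,20,2\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_inspection_table(path)


class TestLoadRateTable:
    def test_long_three_cells_flags_missing(self, tmp_path):
        path = _write(
            tmp_path,
            "long.csv",
            "sector,year,rate\nwine,2000,0.25\nwine,2001,0.3\nhoney,2000,0.1\n",
        )
        table = load_rate_table(path, orientation="long")
        assert len(table.sectors) == 2 and len(table.years) == 2
        assert table.n_missing == 1
        assert np.isnan(table.rate("honey", 2001))

    def test_wide_and_long_orientations_agree(self, tmp_path):
        wide = _write(tmp_path, "wide.csv", "sector,2000,2001\nwine,0.25,0.3\nhoney,0.1,0.2\n")
        long = _write(
            tmp_path,
            "long.csv",
            "sector,year,rate\nwine,2000,0.25\nwine,2001,0.3\nhoney,2000,0.1\nhoney,2001,0.2\n",
        )
        assert load_rate_table(wide, "wide") == load_rate_table(long, "long")

    def test_empty_table_raises_no_data(self, tmp_path):
        path = _write(tmp_path, "empty.csv", "sector,year,rate\n")
        with pytest.raises(ValidationError, match="no data"):
            load_rate_table(path, "long")

    def test_rate_outside_unit_interval_rejected(self, tmp_path):
        path = _write(tmp_path, "bad.csv", "sector,year,rate\nwine,2000,1.2\n")
        with pytest.raises(ValidationError, match=r"outside \[0, 1\]"):
            load_rate_table(path, "long")

    def test_duplicate_sector_year_rejected(self, tmp_path):
        path = _write(
            tmp_path, "dup.csv", "sector,year,rate\nwine,2000,0.2\nwine,2000,0.3\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_rate_table(path, "long")


class TestBuiltinFixture:
    def test_shape_and_spot_rates(self, icqrf):
        totals, rates = icqrf
        assert len(rates.sectors) == 9
        assert rates.years == tuple(range(1997, 2021))
        assert rates.rate("wine", 1997) == 0.321
        assert rates.rate("meat", 2020) == 0.116
        assert rates.n_missing == 0

    def test_sector_totals(self, icqrf):
        per_sector, _ = sector_and_grand_totals(icqrf[0])
        assert per_sector.at["honey", "inspections"] == 12224
        assert per_sector.at["wine", "irregularities"] == 44836

    def test_identical_across_calls(self, icqrf):
        totals2, rates2 = builtin_fixture()
        assert rates2 == icqrf[1]
        assert totals2.records == icqrf[0].records


class TestComputeRates:
    @pytest.mark.parametrize(
        "inspections,irregularities,expected",
        [(100, 25, 0.25), (100, 0, 0.0), (159187, 44836, float(Fraction(44836, 159187)))],
    )
    def test_exact_quotients(self, inspections, irregularities, expected):
        table = InspectionTable([InspectionRecord("wine", 2000, inspections, irregularities)])
        assert compute_rates(table).rate("wine", 2000) == expected

    def test_zero_inspections_cell_marked_missing(self):
        table = InspectionTable(
            [
                InspectionRecord("wine", 2000, 0, 0),
                InspectionRecord("wine", 2001, 10, 1),
            ]
        )
        rates = compute_rates(table)
        assert np.isnan(rates.rate("wine", 2000))
        assert rates.rate("wine", 2001) == 0.1

    @given(
        st.lists(
            st.tuples(st.integers(1, 10_000), st.floats(0, 1)),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_rates_always_satisfy_invariants(self, cells):
        records = [
            InspectionRecord("s", 2000 + i, n, int(round(n * frac)))
            for i, (n, frac) in enumerate(cells)
        ]
        rates = compute_rates(InspectionTable(records))
        values = rates.rates.to_numpy()
        present = values[~np.isnan(values)]
        assert ((present >= 0) & (present <= 1)).all()


class TestTotals:
    def test_empty_table(self):
        frame, grand = sector_and_grand_totals(InspectionTable([]))
        assert grand == (0, 0) and frame.empty

    def test_two_records(self):
        table = InspectionTable(
            [InspectionRecord("a", 2000, 100, 10), InspectionRecord("b", 2000, 50, 5)]
        )
        frame, grand = sector_and_grand_totals(table)
        assert grand == (150, 15)

    def test_grand_equals_sum_of_sector_totals(self, icqrf):
        frame, grand = sector_and_grand_totals(icqrf[0])
        assert grand == (int(frame["inspections"].sum()), int(frame["irregularities"].sum()))


@given(
    rates=st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=12),
    orientation=st.sampled_from(["long", "wide"]),
)
@settings(max_examples=40, deadline=None)
def test_round_trip_preserves_cells_exactly(tmp_path_factory, rates, orientation):
    """Write-then-read reproduces every cell bit-for-bit in both layouts."""
    tmp = tmp_path_factory.mktemp("roundtrip")
    half = len(rates) // 2
    cells = [("alpha", 2000 + i, r) for i, r in enumerate(rates[:half])]
    cells += [("beta", 2000 + i, r) for i, r in enumerate(rates[half:])]
    table = RateTable.from_cells(cells)
    path = tmp / f"t_{orientation}.csv"
    write_rate_table(table, path, orientation)
    again = load_rate_table(path, orientation)
    pd.testing.assert_frame_equal(table.rates, again.rates)
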