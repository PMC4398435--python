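import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings, strategies as st

from lagoshift.env_stack import GridSpec
from lagoshift.occurrence_qc import (
    assign_period,
    deduplicate,
    filter_by_range_polygon,
    filter_resolution,
    haversine_km,
    resolve_taxonomy,
    run_qc_chain,
)


def make_records(**cols):
    base = {
        "species": ["a"],
        "lon": [0.0],
        "lat": [50.0],
        "year": [2000],
        "precision_km": [1.0],
        "source": ["s"],
    }
    n = max(len(v) for v in cols.values()) if cols else 1
    out = {k: (cols.get(k, v * n if len(v) == 1 else v)) for k, v in base.items()}
    return pd.DataFrame(out)


class TestTaxonomy:
    def test_accepted_name_retained_unchanged(self):
        rec = make_records(species=["Lepus timidus"])
        out = resolve_taxonomy(rec, {"Lepus timidus"})
        assert list(out["species"]) == ["Lepus timidus"]

    def test_synonym_remapped(self):
        rec = make_records(species=["Lepus hibernicus"])
        out = resolve_taxonomy(rec, {"Lepus timidus"}, {"Lepus hibernicus": "Lepus timidus"})
        assert list(out["species"]) == ["Lepus timidus"]

    def test_unmatched_dropped_and_counted(self):
        rec = make_records(species=["a", "nope"], lon=[0, 0], lat=[50, 50],
                           year=[2000, 2000], precision_km=[1, 1], source=["s", "s"])
        out = resolve_taxonomy(rec, {"a"})
        assert list(out["species"]) == ["a"]
        assert out.attrs["n_dropped_taxonomy"] == 1

    def test_empty_accepted_set_is_config_error(self):
        with pytest.raises(ValueError):
            resolve_taxonomy(make_records(), set())

    def test_synonym_target_must_be_accepted(self):
        with pytest.raises(ValueError):
            resolve_taxonomy(make_records(), {"a"}, {"x": "not-accepted"})


class TestRangePolygon:
    poly = shapely.box(0.0, 45.0, 10.0, 55.0)

    def test_centroid_kept_tolerance_zero(self):
        rec = make_records(lon=[5.0], lat=[50.0])
        assert len(filter_by_range_polygon(rec, self.poly, 0.0)) == 1

    def test_far_outside_dropped(self):
        rec = make_records(lon=[50.0], lat=[50.0])  # ~2800 km east
        out = filter_by_range_polygon(rec, self.poly, 0.0)
        assert len(out) == 0 and out.attrs["n_dropped_range"] == 1

    def test_within_tolerance_kept_geodesic(self):
        # ~5 km east of the lon=10 boundary at lat 50; haversine oracle below
        lon_off = 5.0 / (111.32 * np.cos(np.radians(50.0)))
        rec = make_records(lon=[10.0 + lon_off], lat=[50.0])
        d_oracle = min(
            haversine_km(rec.lon[0], rec.lat[0], 10.0, b_lat)
            for b_lat in np.linspace(45, 55, 2001)
        )
        assert 4.9 < d_oracle < 5.1
        assert len(filter_by_range_polygon(rec, self.poly, 10.0)) == 1
        assert len(filter_by_range_polygon(rec, self.poly, 1.0)) == 0

    def test_invalid_polygon_rejected(self):
        bowtie = shapely.Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(ValueError, match="invalid"):
            filter_by_range_polygon(make_records(), bowtie)


class TestResolution:
    @pytest.mark.parametrize("precision,kept", [(1.0, True), (2.0, True), (2.5, False)])
    def test_threshold_inclusive_at_2km(self, precision, kept):
        rec = make_records(precision_km=[precision])
        assert len(filter_resolution(rec)) == (1 if kept else 0)

    def test_missing_precision_dropped_by_default_kept_by_config(self):
        rec = make_records(precision_km=[np.nan])
        assert len(filter_resolution(rec)) == 0
        assert len(filter_resolution(rec, keep_missing=True)) == 1


class TestPeriodAssignment:
    @pytest.mark.parametrize("year,period", [(1949, "pre1950"), (1950, "post1950"), (2000, "post1950")])
    def test_cutoff(self, year, period):
        out = assign_period(make_records(year=[year]))
        assert out["period"].iloc[0] == period

    def test_missing_year_dropped_or_assigned(self):
        rec = make_records(year=[np.nan])
        assert len(assign_period(rec)) == 0
        out = assign_period(rec, missing_year="post")
        assert out["period"].iloc[0] == "post1950"


class TestDeduplicate:
    grid = GridSpec(n_rows=20, n_cols=20, cell_size=0.5, x_origin=0.0, y_origin=60.0)

    def dframe(self, rows):
        df = pd.DataFrame(rows, columns=["species", "lon", "lat", "year", "period", "source"])
        df["precision_km"] = 1.0
        return df

    def test_same_cell_same_period_collapses_to_earliest(self):
        df = self.dframe([
            ("a", 0.1, 59.9, 1990, "post1950", "z"),
            ("a", 0.2, 59.8, 1960, "post1950", "y"),
        ])
        out = deduplicate(df, self.grid)
        assert len(out) == 1 and out["year"].iloc[0] == 1960

    def test_same_cell_different_periods_both_kept(self):
        df = self.dframe([
            ("a", 0.1, 59.9, 1940, "pre1950", "s"),
            ("a", 0.1, 59.9, 1990, "post1950", "s"),
        ])
        assert len(deduplicate(df, self.grid)) == 2

    def test_adjacent_cells_both_kept(self):
        df = self.dframe([
            ("a", 0.1, 59.9, 1990, "post1950", "s"),
            ("a", 0.6, 59.9, 1990, "post1950", "s"),
        ])
        assert len(deduplicate(df, self.grid)) == 2

    @given(st.lists(
        st.tuples(st.sampled_from(["a", "b"]),
                  st.floats(0.01, 9.99), st.floats(50.01, 59.99),
                  st.integers(1900, 2000)),
        min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_output_size_matches_set_oracle(self, rows):
        df = self.dframe([(s, lo, la, y, "pre1950" if y < 1950 else "post1950", "s")
                          for s, lo, la, y in rows])
        out = deduplicate(df, self.grid)
        r, c = self.grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        expected = len({(s, ri, ci, p) for s, ri, ci, p in
                        zip(df["species"], r, c, df["period"])})
        assert len(out) == expected

    def test_order_invariance(self):
        df = self.dframe([
            ("a", 0.1, 59.9, 1990, "post1950", "b"),
            ("a", 0.2, 59.8, 1990, "post1950", "a"),
            ("a", 3.0, 55.0, 1980, "post1950", "c"),
        ])
        out1 = deduplicate(df, self.grid)
        out2 = deduplicate(df.iloc[::-1], self.grid)
        assert sorted(out1["source"]) == sorted(out2["source"]) == ["a", "c"]


class TestChain:
    def test_idempotent_and_subset(self, records):
        grid = GridSpec(n_rows=20, n_cols=20, cell_size=0.5, x_origin=0.0, y_origin=60.0)
        clean1, report = run_qc_chain(records, {"a", "b"}, grid)
        clean2, _ = run_qc_chain(clean1, {"a", "b"}, grid)
        pd.testing.assert_frame_equal(
            clean1.reset_index(drop=True), clean2.reset_index(drop=True)
        )
        # no fabrication: every (lon, lat, year) from the output is in the input
        merged = clean1.merge(records, on=["lon", "lat", "year"], how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        assert set(report["species"]) == {"a", "b"}
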