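"""Population weights, county means, coverage flags, record assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatstack.county import (
    METRIC_FAMILIES,
    TABLE_COLUMNS,
    CountyRectangle,
    assemble_records,
    build_weights,
    coverage_flag,
    epoch_for_year,
    weighted_mean,
)


def grid():
    return np.array([0.05, 0.15]), np.array([0.05, 0.15])  # 2×2 cells


class TestBuildWeights:
    def test_proportionality_90_10(self):
        lats, lons = grid()
        county = CountyRectangle("01001", 0.0, 0.2, 0.0, 0.2)
        pts = pd.DataFrame({
            "lon": [0.05, 0.15], "lat": [0.05, 0.05], "pop": [90, 10]})
        w = build_weights(pts, [county], lats, lons, "2000")
        assert sorted(w["weight"]) == [0.1, 0.9]
        assert w["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_county_within_single_cell(self):
        lats, lons = grid()
        county = CountyRectangle("01001", 0.0, 0.1, 0.0, 0.1)
        pts = pd.DataFrame({"lon": [0.04, 0.06], "lat": [0.03, 0.07], "pop": [5, 7]})
        w = build_weights(pts, [county], lats, lons, "2000")
        assert len(w) == 1 and w["weight"].iloc[0] == 1.0

    def test_ten_percent_worked_example(self):
        # a cell holding 10% of the county population gets weight 0.10
        lats, lons = grid()
        county = CountyRectangle("01001", 0.0, 0.2, 0.0, 0.2)
        pts = pd.DataFrame({"lon": [0.05, 0.15, 0.15], "lat": [0.05, 0.05, 0.15],
                            "pop": [50, 400, 50]})
        w = build_weights(pts, [county], lats, lons, "2000").set_index(["cell_row", "cell_col"])
        assert w.loc[(0, 0), "weight"] == pytest.approx(0.10)

    def test_zero_population_uniform_with_warning(self, caplog):
        lats, lons = grid()
        county_a = CountyRectangle("01001", 0.0, 0.1, 0.0, 0.2)
        county_b = CountyRectangle("01003", 0.1, 0.2, 0.0, 0.2)
        pts = pd.DataFrame({"lon": [0.15], "lat": [0.05], "pop": [10]})
        with caplog.at_level("WARNING"):
            w = build_weights(pts, [county_a, county_b], lats, lons, "2000")
        wa = w[w["fips"] == "01001"]
        assert np.allclose(wa["weight"], 0.5)
        assert "zero population" in caplog.text

    def test_unassigned_point_rejected(self):
        lats, lons = grid()
        county = CountyRectangle("01001", 0.0, 0.1, 0.0, 0.2)
        pts = pd.DataFrame({"lon": [0.5], "lat": [0.05], "pop": [1]})
        with pytest.raises(ValueError, match="exactly one county"):
            build_weights(pts, [county], lats, lons, "2000")


class TestWeightedMean:
    def test_basic(self):
        v, cov = weighted_mean([20.0, 30.0], [0.9, 0.1])
        assert v == pytest.approx(21.0) and cov == 1.0

    def test_renormalizes_over_missing(self):
        v, cov = weighted_mean([20.0, np.nan], [0.9, 0.1])
        assert v == pytest.approx(20.0) and cov == pytest.approx(0.9)

    def test_all_missing(self):
        v, cov = weighted_mean([np.nan, np.nan], [0.9, 0.1])
        assert np.isnan(v) and cov == 0.0

    def test_matches_per_point_brute_force(self, rng):
        """County mean equals assigning each population point its cell's
        value and averaging over people."""
        lats = np.arange(0.05, 1.0, 0.1)
        lons = np.arange(0.05, 1.0, 0.1)
        county = CountyRectangle("01001", 0.0, 1.0, 0.0, 1.0)
        pts = pd.DataFrame({
            "lon": rng.uniform(0, 1, 500), "lat": rng.uniform(0, 1, 500),
            "pop": rng.integers(1, 40, 500)})
        w = build_weights(pts, [county], lats, lons, "2000")
        field = rng.normal(20, 5, (len(lats), len(lons)))
        vals = field[w["cell_row"], w["cell_col"]]
        mine, cov = weighted_mean(vals, w["weight"].to_numpy())
        ir = np.clip(((pts["lat"]) // 0.1).astype(int), 0, 9)
        ic = np.clip(((pts["lon"]) // 0.1).astype(int), 0, 9)
        brute = np.average(field[ir, ic], weights=pts["pop"])
        assert mine == pytest.approx(brute, abs=1e-9)
        assert cov == pytest.approx(1.0, abs=1e-12)


class TestCoverageFlag:
    @pytest.mark.parametrize("cov, flag", [
        (1.0, 0), (0.50, 0), (0.49999, 1), (0.10, 1), (0.099, 2),
        (1e-9, 2), (0.0, 3),
    ])
    def test_boundaries(self, cov, flag):
        assert coverage_flag(cov) == flag

    @given(cov=st.floats(0, 1, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_partition_no_gaps(self, cov):
        assert coverage_flag(cov) in (0, 1, 2, 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            coverage_flag(1.5)


class TestEpochs:
    def test_year_boundary(self):
        assert epoch_for_year(2009) == "2000"
        assert epoch_for_year(2010) == "2015"


def _daily_dataset(dates, shape, fill):
    import xarray as xr
    data = np.full((len(dates),) + shape, fill, dtype=float)
    dims = ("date", "y", "x")
    return xr.Dataset({k: (dims, data.copy()) for k in ("min", "max", "mean")}
                      | {"count": (dims, np.full(data.shape, 24, dtype=int))},
                      coords={"date": np.asarray(dates, dtype="datetime64[D]")})


def _weight_table(epoch, weight_cells):
    return pd.DataFrame([("01001", r, c, w, epoch) for r, c, w in weight_cells],
                        columns=["fips", "cell_row", "cell_col", "weight", "epoch"])


class TestAssembleRecords:
    def make_inputs(self, n_dates=5, value=20.0):
        dates = np.datetime64("2020-07-01") + np.arange(n_dates)
        daily = {f: _daily_dataset(dates, (2, 2), value) for f in METRIC_FAMILIES}
        rows = []
        for fips, cells in [("01001", [(0, 0, 0.5), (0, 1, 0.5)]),
                            ("01003", [(1, 0, 1.0)]),
                            ("02013", [(1, 1, 1.0)])]:
            for r, c, w in cells:
                for epoch in ("2000", "2015"):
                    rows.append((fips, r, c, w, epoch))
        weights = pd.DataFrame(rows, columns=["fips", "cell_row", "cell_col",
                                              "weight", "epoch"])
        return daily, weights

    def test_schema_shape_and_columns(self):
        daily, weights = self.make_inputs()
        rec = assemble_records(daily, weights)
        assert rec.shape == (15, 30)
        assert list(rec.columns) == list(TABLE_COLUMNS)
        assert rec["Date"].iloc[0] == "20200701"

    def test_complete_input_all_flags_zero(self):
        daily, weights = self.make_inputs()
        rec = assemble_records(daily, weights)
        for fam in METRIC_FAMILIES:
            assert (rec[f"Flag_{fam}"] == 0).all()

    def test_epoch_switch_uses_correct_table(self):
        dates = [np.datetime64("2009-12-31"), np.datetime64("2010-01-01")]
        daily = {f: _daily_dataset(dates, (1, 2), 10.0) for f in METRIC_FAMILIES}
        for f in METRIC_FAMILIES:
            daily[f]["mean"][:, 0, 1] = 30.0
            daily[f]["min"][:, 0, 1] = 30.0
            daily[f]["max"][:, 0, 1] = 30.0
        w = pd.concat([
            _weight_table("2000", [(0, 0, 1.0)]),         # all weight west
            _weight_table("2015", [(0, 0, 0.5), (0, 1, 0.5)]),
        ])
        rec = assemble_records(daily, w).set_index("Date")
        assert rec.loc["20091231", "Tmean_C"] == pytest.approx(10.0)
        assert rec.loc["20100101", "Tmean_C"] == pytest.approx(20.0)

    def test_changing_unused_epoch_changes_nothing(self):
        daily, weights = self.make_inputs()
        rec1 = assemble_records(daily, weights)
        w2 = weights.copy()
        w2.loc[w2["epoch"] == "2000", "weight"] = 0.123  # dates are all 2020
        rec2 = assemble_records(daily, w2)
        pd.testing.assert_frame_equal(rec1, rec2)

    def test_all_missing_county_dropped_by_default(self):
        daily, weights = self.make_inputs()
        for f in METRIC_FAMILIES:
            for stat in ("min", "max", "mean"):
                daily[f][stat][:, 1, 1] = np.nan   # county 02013's only cell
        rec = assemble_records(daily, weights)
        assert "02013" not in set(rec["StCoFIPS"])
        kept = assemble_records(daily, weights, drop_all_missing=False)
        sub = kept[kept["StCoFIPS"] == "02013"]
        assert (sub[[f"Flag_{f}" for f in METRIC_FAMILIES]] == 3).all().all()
        assert sub["Tmean_C"].isna().all()

    def test_missing_family_rejected(self):
        daily, weights = self.make_inputs()
        del daily["UTCI"]
        with pytest.raises(ValueError, match="missing"):
            assemble_records(daily, weights)
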