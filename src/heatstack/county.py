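"""Population weights, county means, coverage flags, and record assembly.

A county's daily value for a metric is the population-weighted mean of the
grid cells intersecting it, with the weight of a cell equal to the fraction
of the county's population residing in that cell.  When some cells are
missing, the mean renormalizes over the non-missing weights and the summed
non-missing weight becomes the *coverage*.  Coverage is flagged ordinally:
0 (≥50% of the population represented), 1 (10–49%), 2 (<10%), 3 (nothing —
the value itself is missing).  Two weight epochs account for population
shifts; the epoch is selected by calendar year.

County identifiers are 5-character zero-padded FIPS strings throughout —
never integers, to preserve leading-zero state codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "METRIC_FAMILIES",
    "TABLE_COLUMNS",
    "CountyRectangle",
    "build_weights",
    "weighted_mean",
    "unweighted_mean",
    "coverage_flag",
    "epoch_for_year",
    "assemble_records",
]

log = logging.getLogger(__name__)

#: Metric families in output order; each contributes min/max/mean columns
#: and one flag column.
METRIC_FAMILIES = ("T", "TD", "NET", "HI", "HX", "WBGT", "UTCI")

TABLE_COLUMNS = (
    ["StCoFIPS", "Date"]
    + [f"{fam}{s}_C" for fam in METRIC_FAMILIES for s in ("min", "max", "mean")]
    + [f"Flag_{fam}" for fam in METRIC_FAMILIES]
)


@dataclass
class CountyRectangle:
    """Toy areal unit: an axis-aligned lat/lon rectangle with a FIPS code."""

    fips: str
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def contains(self, lon, lat):
        return (
            (lon >= self.lon_min) & (lon < self.lon_max)
            & (lat >= self.lat_min) & (lat < self.lat_max)
        )


def _cell_of(points_lon, points_lat, grid_lat, grid_lon):
    """Row/col of the nearest grid centroid for each point."""
    def nearest(coords, x):
        coords = np.asarray(coords, dtype=float)
        d = np.abs(x[:, None] - coords[None, :])
        return np.argmin(d, axis=1)
    return nearest(grid_lat, np.asarray(points_lat, float)), nearest(grid_lon, np.asarray(points_lon, float))


def build_weights(points: pd.DataFrame, counties, grid_lat, grid_lon, epoch):
    """Population weights per (county, cell) for one population epoch.

    Parameters
    ----------
    points : DataFrame with columns lon, lat, pop
        High-resolution population counts at point locations.  Every point
        must fall in exactly one county.
    counties : iterable of CountyRectangle
    grid_lat, grid_lon : 1-D arrays
        Grid-cell centroid coordinates.
    epoch : str
        Population-epoch label stored on every row.

    Returns
    -------
    DataFrame with columns (fips, cell_row, cell_col, weight, epoch);
    weights per county sum to 1.  A county with zero total population gets
    uniform weights over the grid cells intersecting its rectangle, with a
    warning.
    """
    lon = points["lon"].to_numpy(float)
    lat = points["lat"].to_numpy(float)
    pop = points["pop"].to_numpy(float)
    rows, cols = _cell_of(lon, lat, grid_lat, grid_lon)

    assigned = np.zeros(len(points), dtype=int)
    out = []
    for county in counties:
        inside = county.contains(lon, lat)
        assigned += inside
        total = pop[inside].sum()
        if total <= 0:
            cells = _intersecting_cells(county, grid_lat, grid_lon)
            if not len(cells):
                log.warning("county %s intersects no grid cells", county.fips)
                continue
            log.warning("county %s has zero population; uniform weights over %d cells",
                        county.fips, len(cells))
            for r, c in cells:
                out.append((county.fips, r, c, 1.0 / len(cells), epoch))
            continue
        sub = pd.DataFrame({"r": rows[inside], "c": cols[inside], "pop": pop[inside]})
        agg = sub.groupby(["r", "c"], sort=True)["pop"].sum()
        for (r, c), p in agg.items():
            out.append((county.fips, int(r), int(c), p / total, epoch))
    if np.any(assigned != 1):
        n_bad = int(np.count_nonzero(assigned != 1))
        raise ValueError(f"{n_bad} population points not assigned to exactly one county")
    return pd.DataFrame(out, columns=["fips", "cell_row", "cell_col", "weight", "epoch"])


def _intersecting_cells(county: CountyRectangle, grid_lat, grid_lon):
    grid_lat = np.asarray(grid_lat, float)
    grid_lon = np.asarray(grid_lon, float)
    dlat = np.median(np.abs(np.diff(grid_lat))) if len(grid_lat) > 1 else 1.0
    dlon = np.median(np.abs(np.diff(grid_lon))) if len(grid_lon) > 1 else 1.0
    rs = np.nonzero((grid_lat + dlat / 2 > county.lat_min) & (grid_lat - dlat / 2 < county.lat_max))[0]
    cs = np.nonzero((grid_lon + dlon / 2 > county.lon_min) & (grid_lon - dlon / 2 < county.lon_max))[0]
    return [(int(r), int(c)) for r in rs for c in cs]


def weighted_mean(cell_values, weights):
    """Renormalized population-weighted mean and its coverage.

    Parameters
    ----------
    cell_values : 1-D array
        Metric value per weight-table row (NaN = missing).
    weights : 1-D array
        Population weights for one (county, epoch), summing to 1.

    Returns
    -------
    (value, coverage) — value is NaN when coverage is 0; coverage is the
    summed weight on non-missing cells.
    """
    v = np.asarray(cell_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = np.isfinite(v)
    coverage = float(w[ok].sum())
    if coverage <= 0.0:
        return np.nan, 0.0
    return float((v[ok] * w[ok]).sum() / coverage), coverage


def unweighted_mean(cell_values):
    """Simple average over a county's cells, with cell-count coverage."""
    v = np.asarray(cell_values, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        return np.nan, 0.0
    return float(v[ok].mean()), float(ok.mean())


def coverage_flag(coverage):
    """Ordinal coverage flag: ≥0.50 → 0, [0.10, 0.50) → 1, (0, 0.10) → 2,
    exactly 0 → 3."""
    cov = np.asarray(coverage, dtype=float)
    if np.any((cov < 0) | (cov > 1 + 1e-9)):
        raise ValueError("coverage outside [0, 1]")
    out = np.select([cov >= 0.50, cov >= 0.10, cov > 0.0], [0, 1, 2], default=3)
    return out if out.ndim else int(out)


def epoch_for_year(year, boundary=2010, epochs=("2000", "2015")):
    """Population epoch label for a calendar year (default: <2010 → first)."""
    return epochs[0] if year < boundary else epochs[1]


def aggregate_day(field, weights_epoch: pd.DataFrame, weighted=True):
    """County means of one daily raster for every county in a weight table.

    ``field`` is a 2-D (lat, lon) array; returns DataFrame (fips, value,
    coverage).
    """
    rows = []
    for fips, grp in weights_epoch.groupby("fips", sort=True):
        vals = field[grp["cell_row"].to_numpy(), grp["cell_col"].to_numpy()]
        if weighted:
            value, cov = weighted_mean(vals, grp["weight"].to_numpy())
        else:
            value, cov = unweighted_mean(vals)
        rows.append((fips, value, cov))
    return pd.DataFrame(rows, columns=["fips", "value", "coverage"])


def assemble_records(daily_by_family, weights: pd.DataFrame, epoch_boundary=2010,
                     epochs=("2000", "2015"), weighted=True, drop_all_missing=True):
    """Build the output table: one row per (county, local day).

    Parameters
    ----------
    daily_by_family : dict
        ``{family: xarray.Dataset}`` from :func:`heatstack.temporal.daily_stats`
        for each family in :data:`METRIC_FAMILIES` (vars min/max/mean with
        dims (date, lat-like, lon-like)).
    weights : DataFrame
        Weight table with an ``epoch`` column covering both epochs.
    drop_all_missing : bool
        Drop counties whose rows are all-flag-3 for every family on every
        day (the default); otherwise keep them as flagged missing rows.

    Returns
    -------
    DataFrame with exactly the published schema columns, ``Date`` formatted
    YYYYMMDD and FIPS as zero-padded strings.
    """
    missing = [f for f in METRIC_FAMILIES if f not in daily_by_family]
    if missing:
        raise ValueError(f"metric families missing from input: {missing}")
    dates = np.asarray(daily_by_family["T"]["date"].values, dtype="datetime64[D]")
    for fam, ds in daily_by_family.items():
        if not np.array_equal(np.asarray(ds["date"].values, dtype="datetime64[D]"), dates):
            raise ValueError(f"date axis of family {fam} differs from T")

    records = {}
    for di, date in enumerate(dates):
        year = date.astype("datetime64[Y]").astype(int) + 1970
        epoch = epoch_for_year(int(year), epoch_boundary, epochs)
        wtab = weights[weights["epoch"] == epoch]
        if wtab.empty:
            raise ValueError(f"no weights for epoch {epoch}")
        date_str = pd.Timestamp(date).strftime("%Y%m%d")
        for fam in METRIC_FAMILIES:
            ds = daily_by_family[fam]
            per_stat = {}
            for stat in ("min", "max", "mean"):
                field = np.asarray(ds[stat].isel(date=di).values)
                per_stat[stat] = aggregate_day(field, wtab, weighted=weighted)
            # coverage identical across the three stats (same missing cells)
            agg = per_stat["mean"]
            for fips, vmin, vmax, vmean, cov in zip(
                agg["fips"], per_stat["min"]["value"], per_stat["max"]["value"],
                agg["value"], agg["coverage"]
            ):
                row = records.setdefault((fips, date_str), {})
                row[f"{fam}min_C"] = vmin
                row[f"{fam}max_C"] = vmax
                row[f"{fam}mean_C"] = vmean
                row[f"Flag_{fam}"] = coverage_flag(cov)

    df = pd.DataFrame(
        [{"StCoFIPS": fips, "Date": d, **vals} for (fips, d), vals in sorted(records.items())]
    )
    if drop_all_missing and len(df):
        all3 = np.ones(len(df), dtype=bool)
        for fam in METRIC_FAMILIES:
            all3 &= df[f"Flag_{fam}"] == 3
        dropped = df.loc[all3, "StCoFIPS"].unique()
        gone = [f for f in dropped if (df.loc[df["StCoFIPS"] == f, [f"Flag_{x}" for x in METRIC_FAMILIES]] == 3).all().all()]
        if gone:
            log.info("dropping %d all-missing counties: %s", len(gone), gone)
            df = df[~df["StCoFIPS"].isin(gone)]
    df = df.reindex(columns=TABLE_COLUMNS)
    if df[["StCoFIPS", "Date"]].isna().any().any():
        raise ValueError("record assembly produced incomplete keys")
    return df.reset_index(drop=True)
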