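"""Radiation de-accumulation, UTC→local-day alignment, and daily statistics.

Reanalysis radiation arrives as energy accumulated over a window (J/m²);
:func:`deaccumulate` converts it back to hourly-mean fluxes.  Local-day
handling works through per-cell integer UTC-offset maps — one for local
standard time (LST), one for local daylight time (LDT) — organized in
validity periods so that cells whose time zone changed mid-record (the
Indiana mechanism) use the period-appropriate map.  Daily minimum, maximum
and mean are computed over the 24 local hours 00–23, with a cell-variable-day
marked missing when fewer than 21 hourly values are available; the mean is
taken over the available hours.

Daily extremes from hourly data can miss between-hour extremes; this is a
property of hourly inputs and is documented, not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "MIN_HOURS_PER_DAY",
    "deaccumulate",
    "nearest_neighbor_regrid",
    "OffsetSchedule",
    "dst_bounds",
    "local_day_index",
    "daily_stats",
]

log = logging.getLogger(__name__)

#: Minimum non-missing hourly observations for a valid daily statistic.
MIN_HOURS_PER_DAY = 21


def deaccumulate(accumulated, window=24, axis=0, tol=1.0, allow_negative=False):
    """Convert window-accumulated energy (J/m²) to hourly-mean flux (W/m²).

    Successive differences along ``axis`` divided by 3600; the first step of
    each accumulation window takes the raw value.  The series must start at
    a window boundary.  For sign-definite accumulations (solar fluxes) a
    negative difference beyond ``tol`` J/m² is marked missing (with a
    diagnostic) and smaller ones are clipped to zero; ``allow_negative``
    disables that check for fluxes that may genuinely be negative (net
    thermal radiation).
    """
    acc = np.asarray(accumulated, dtype=float)
    acc = np.moveaxis(acc, axis, 0)
    diff = np.empty_like(acc)
    diff[0] = acc[0]
    diff[1:] = acc[1:] - acc[:-1]
    resets = np.arange(acc.shape[0]) % window == 0
    diff[resets] = acc[resets]
    if allow_negative:
        flux = diff / 3600.0
    else:
        bad = diff < -tol
        if np.any(bad):
            log.warning("deaccumulate: %d negative accumulation steps marked missing",
                        int(np.count_nonzero(bad)))
        flux = np.where(bad, np.nan, np.maximum(diff, 0.0)) / 3600.0
    return np.moveaxis(flux, 0, axis)


def _nearest_index(coarse, fine):
    """Index of the nearest coarse coordinate for each fine coordinate.

    Exact midpoint ties resolve to the smaller index.
    """
    coarse = np.asarray(coarse, dtype=float)
    order = np.argsort(coarse, kind="stable")
    cs = coarse[order]
    pos = np.searchsorted(cs, fine)
    pos = np.clip(pos, 1, len(cs) - 1)
    left, right = cs[pos - 1], cs[pos]
    take_right = (fine - left) > (right - fine)   # tie → left (smaller index)
    idx = np.where(take_right, pos, pos - 1)
    return order[idx]


def nearest_neighbor_regrid(coarse_values, coarse_lat, coarse_lon, fine_lat, fine_lon):
    """Nearest-neighbor regridding between regular lat/lon grids.

    ``coarse_values`` has trailing dims (lat, lon); the result replaces them
    with (fine_lat, fine_lon).  Each fine cell takes the value of the
    nearest coarse centroid; midpoint ties break toward the smaller index.
    """
    ilat = _nearest_index(coarse_lat, np.asarray(fine_lat, dtype=float))
    ilon = _nearest_index(coarse_lon, np.asarray(fine_lon, dtype=float))
    return np.asarray(coarse_values)[..., ilat[:, None], ilon[None, :]]


def dst_bounds(year):
    """US statutory daylight-saving bounds (start, end) as numpy datetimes.

    2000–2006: first Sunday of April to last Sunday of October;
    2007 onward: second Sunday of March to first Sunday of November.
    Both transitions at 02:00 local standard time.
    """
    def nth_sunday(y, month, n):
        d = np.datetime64(f"{y:04d}-{month:02d}-01")
        dow = (d.astype("datetime64[D]").astype(int) + 3) % 7  # 0 = Monday
        first_sunday = 1 + (6 - dow) % 7
        return np.datetime64(f"{y:04d}-{month:02d}-{first_sunday + 7*(n-1):02d}T02:00")

    def last_sunday(y, month):
        next_month = np.datetime64(f"{y:04d}-{month+1:02d}-01", "D")
        last = next_month - np.timedelta64(1, "D")
        dow = (last.astype(int) + 3) % 7
        day = last - np.timedelta64((dow + 1) % 7, "D")
        return np.datetime64(str(day) + "T02:00")

    if year < 2007:
        return nth_sunday(year, 4, 1), last_sunday(year, 10)
    return nth_sunday(year, 3, 2), nth_sunday(year, 11, 1)


@dataclass
class OffsetSchedule:
    """Per-cell UTC offsets with validity periods and a DST calendar.

    ``periods`` maps an inclusive year range to a pair of integer offset
    rasters (LST, LDT).  Offsets must be integer hours in [−12, +14];
    half-hour zones are rejected at construction.
    """

    periods: list = field(default_factory=list)  # (year_lo, year_hi, lst, ldt)
    use_dst: bool = True

    def __post_init__(self):
        for y0, y1, lst, ldt in self.periods:
            for name, arr in (("LST", lst), ("LDT", ldt)):
                a = np.asarray(arr)
                if not np.issubdtype(a.dtype, np.integer):
                    if not np.allclose(a, np.round(a)):
                        raise ValueError(f"{name} offsets must be integer hours "
                                         "(half-hour zones unsupported)")
                if np.any((a < -12) | (a > 14)):
                    raise ValueError(f"{name} offsets outside [-12, +14]")

    def _maps_for_year(self, year):
        for y0, y1, lst, ldt in self.periods:
            if y0 <= year <= y1:
                return np.asarray(lst, dtype=np.int64), np.asarray(ldt, dtype=np.int64)
        raise KeyError(f"no offset map period covers year {year}")

    def offsets_for(self, times):
        """Integer UTC offsets, shape (time, *cell_shape).

        DST applicability is decided per cell on the local **standard**
        clock, between the statutory bounds of each year.
        """
        times = np.asarray(times, dtype="datetime64[s]")
        years = times.astype("datetime64[Y]").astype(int) + 1970
        out = np.empty((len(times),) + np.shape(self.periods[0][2]), dtype=np.int64)
        for year in np.unique(years):
            sel = years == year
            lst, ldt = self._maps_for_year(int(year))
            t = times[sel][:, None]
            if self.use_dst:
                start, end = dst_bounds(int(year))
                local_std = t + lst.reshape(1, -1) * np.timedelta64(3600, "s")
                in_dst = (local_std >= start) & (local_std < end)
                offs = np.where(in_dst, ldt.reshape(1, -1), lst.reshape(1, -1))
            else:
                offs = np.broadcast_to(lst.reshape(1, -1), (int(sel.sum()), lst.size))
            out[sel] = offs.reshape((-1,) + lst.shape)
        return out


def local_day_index(times, offsets):
    """(local_day, local_hour) integer arrays for UTC times and offsets.

    ``local_day`` counts days since the Unix epoch on each cell's local
    clock; broadcasting follows ``offsets`` (time first).
    """
    secs = np.asarray(times, dtype="datetime64[s]").astype("int64")
    secs = secs.reshape((-1,) + (1,) * (np.ndim(offsets) - 1))
    local = secs + np.asarray(offsets, dtype="int64") * 3600
    return local // 86400, (local % 86400) // 3600


def daily_stats(values, times, schedule: OffsetSchedule, min_hours=MIN_HOURS_PER_DAY):
    """Per-cell local-day min/max/mean with the completeness rule.

    Parameters
    ----------
    values : ndarray (time, *cell_shape)
        Hourly metric values (NaN = missing).
    times : array of datetime64
        UTC timestamps, hourly, contiguous.
    schedule : OffsetSchedule
    min_hours : int
        A cell-day with fewer non-missing hours is missing (default 21).

    Returns
    -------
    xarray.Dataset
        Variables ``min``, ``max``, ``mean``, ``count`` with dims
        ``(date, *cell dims)``.  Local days whose 24-hour window is not
        fully covered by the UTC span are excluded and reported in the
        ``incomplete_days`` attribute rather than silently truncated.
    """
    values = np.asarray(values, dtype=float)
    cell_shape = values.shape[1:]
    ncell = int(np.prod(cell_shape))
    offsets = schedule.offsets_for(times).reshape(len(times), ncell)
    day, _ = local_day_index(times, offsets)

    flat = values.reshape(len(times), ncell)
    df = pd.DataFrame({
        "cell": np.tile(np.arange(ncell), len(times)),
        "day": day.ravel(),
        "value": flat.ravel(),
    })
    g = df.groupby(["cell", "day"], sort=True)["value"]
    stats = g.agg(n_hours="size", count="count", vmin="min", vmax="max", vmean="mean")

    complete = stats["n_hours"] == 24
    incomplete_days = sorted(
        {int(d) for d in stats.index.get_level_values("day")[~complete]}
    )
    stats = stats[complete]
    enough = stats["count"] >= min_hours
    stats.loc[~enough, ["vmin", "vmax", "vmean"]] = np.nan

    days = np.array(sorted(stats.index.get_level_values("day").unique()))
    shape = (len(days),) + cell_shape
    out = {k: np.full(shape, np.nan) for k in ("min", "max", "mean")}
    count = np.zeros(shape, dtype=np.int64)
    day_pos = {d: i for i, d in enumerate(days)}
    idx_day = np.array([day_pos[d] for d in stats.index.get_level_values("day")])
    idx_cell = stats.index.get_level_values("cell").to_numpy()
    cell_idx = np.unravel_index(idx_cell, cell_shape) if cell_shape else ()
    out["min"][(idx_day,) + cell_idx] = stats["vmin"]
    out["max"][(idx_day,) + cell_idx] = stats["vmax"]
    out["mean"][(idx_day,) + cell_idx] = stats["vmean"]
    count[(idx_day,) + cell_idx] = stats["count"]

    dims = ("date",) + tuple(f"dim{i}" for i in range(len(cell_shape)))
    dates = days.astype("datetime64[D]")
    ds = xr.Dataset(
        {k: (dims, v) for k, v in out.items()} | {"count": (dims, count)},
        coords={"date": dates},
        attrs={"incomplete_days": [str(np.datetime64(int(d), "D")) for d in incomplete_days]},
    )
    return ds
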