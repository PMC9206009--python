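"""Deterministic synthetic fixtures: gridded meteorology, land cover,
UTC-offset maps, toy counties, and population points.

The generator emulates the structure of hourly reanalysis fields over a
small lat/lon grid: a diurnal temperature cycle peaking mid-afternoon with
autoregressive weather noise, dew points tied to temperature through a
preset humidity regime, solar radiation consistent with the astronomical
position of the sun (zero at night, direct ≤ total), longwave fluxes from
an effective sky temperature, bounded AR(1) winds, and pressure set by a
preset station elevation.  Radiation is written as energy accumulated over
the UTC day (J/m²), the reanalysis convention, so the ingest path exercises
de-accumulation.

Three climate presets cover the regimes the metrics must handle:
``summer-humid`` (warm, moist, light wind), ``desert-dry`` (hot, very dry —
produces hours below 5% relative humidity — and high-elevation, low
pressure), and ``coastal-windy`` (mild, windy — produces hours above the
17 m/s UTCI cap).

Everything is drawn from one seeded generator: identical config + seed
gives identical fixtures, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from .county import CountyRectangle
from .solar import solar_position
from .temporal import OffsetSchedule

__all__ = ["SynthConfig", "PRESETS", "gen_meteo", "gen_land_cover",
           "gen_offsets", "gen_counties", "write_fixture"]

_SIGMA = 5.67e-8

PRESETS = {
    # t_mean °C, diurnal amplitude °C, dew-point depression °C (mean, sd),
    # wind mean/sd m/s, elevation m, clear-sky transmittance, cloud range
    "summer-humid": dict(t_mean=26.0, t_amp=6.0, dep_mean=3.0, dep_sd=1.5,
                         wind_mean=3.0, wind_sd=1.5, elev=200.0, tau=0.65,
                         cloud_lo=0.55, sky_emis=0.85),
    "desert-dry": dict(t_mean=33.0, t_amp=10.0, dep_mean=38.0, dep_sd=9.0,
                       wind_mean=3.5, wind_sd=2.0, elev=1600.0, tau=0.75,
                       cloud_lo=0.9, sky_emis=0.70),
    "coastal-windy": dict(t_mean=24.0, t_amp=5.0, dep_mean=4.0, dep_sd=2.0,
                          wind_mean=11.0, wind_sd=4.0, elev=10.0, tau=0.55,
                          cloud_lo=0.35, sky_emis=0.80),
}


@dataclass
class SynthConfig:
    """Configuration of one synthetic fixture.

    The defaults define the standard test grid: 10×10 cells at 0.1°
    spacing, 35 summer days, three counties spanning two time zones.
    """

    n_lat: int = 10
    n_lon: int = 10
    lat0: float = 36.0
    lon0: float = -90.0
    dlat: float = 0.1
    dlon: float = 0.1
    start: str = "2020-07-01"
    n_days: int = 35
    seed: int = 0
    preset: str = "summer-humid"
    n_counties: int = 3
    populations: tuple = (1000, 2000, 500)
    dst: bool = True
    tz_west_offset: int = -6
    tz_east_offset: int = -5
    tz_boundary_frac: float = 0.5
    tz_change_year: int | None = None
    # missing-data injection
    ocean_cells: tuple = ()            # (row, col) pairs masked everywhere
    hole_fraction: float = 0.0         # fraction of cell-days with hour holes
    hole_hours_max: int = 6

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    @property
    def lats(self):
        return self.lat0 + self.dlat * np.arange(self.n_lat)

    @property
    def lons(self):
        return self.lon0 + self.dlon * np.arange(self.n_lon)

    @property
    def times(self):
        t0 = np.datetime64(self.start + "T00:00", "s")
        return t0 + np.timedelta64(3600, "s") * np.arange(self.n_days * 24 + 1)[1:]

    @property
    def tz_boundary_lon(self):
        return self.lon0 + self.dlon * self.n_lon * self.tz_boundary_frac


def _ar1(rng, shape, rho=0.9, sd=1.0):
    """AR(1) noise along the first axis, stationary variance sd²."""
    out = np.empty(shape)
    out[0] = rng.normal(0.0, sd, shape[1:])
    innov_sd = sd * np.sqrt(1 - rho**2)
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + rng.normal(0.0, innov_sd, shape[1:])
    return out


def gen_meteo(cfg: SynthConfig) -> xr.Dataset:
    """Hourly gridded meteorology for the configured fixture.

    Returns an (time, lat, lon) dataset with ERA5-style names and units:
    t2m/d2m (K), sp (Pa), u10/v10 (m/s), and ssrd/ssr/strd/str_net/fdir
    accumulated over the UTC day (J/m²).
    """
    p = PRESETS[cfg.preset]
    rng = np.random.default_rng(cfg.seed)
    times, lats, lons = cfg.times, cfg.lats, cfg.lons
    nt, ny, nx = len(times), len(lats), len(lons)
    shape = (nt, ny, nx)

    lon3 = lons[None, None, :]
    lat3 = lats[None, :, None]
    hour_utc = (times.astype("datetime64[s]").astype("int64") % 86400) / 3600.0
    h_solar = hour_utc[:, None, None] + lon3 / 15.0

    diurnal = p["t_amp"] * np.sin(2 * np.pi * (h_solar - 9.0) / 24.0)
    t_air = (p["t_mean"] - 0.6 * (lat3 - lats.mean()) + diurnal
             + _ar1(rng, shape, rho=0.95, sd=1.0))
    if np.any(~np.isfinite(t_air)):
        raise ValueError("infeasible meteorology configuration")

    depression = np.clip(p["dep_mean"] + _ar1(rng, shape, rho=0.9, sd=p["dep_sd"])
                         + 0.35 * np.clip(diurnal, 0, None), 0.1, None)
    t_dew = t_air - depression
    if np.any(t_dew > t_air):
        raise ValueError("dew point above air temperature")

    # radiation consistent with solar geometry: mean cosine zenith over the
    # hour ending at each timestamp (60 subsamples, zero at night)
    offs = (3600.0 * (np.arange(60) + 0.5) / 60.0).astype("timedelta64[s]")
    sub = times[:, None] - offs
    ctx = solar_position(lat3[..., None], lon3[..., None], sub[:, None, None, :])
    cza_hour = np.maximum(ctx.cza, 0.0).mean(axis=-1)

    cloud = np.clip(1.0 - np.abs(_ar1(rng, shape, rho=0.97, sd=0.35)),
                    p["cloud_lo"], 1.0)
    ssrd = p["tau"] * 1367.0 * cza_hour * cloud
    fdir = 0.7 * cloud * ssrd
    ssr = 0.8 * ssrd
    tk = t_air + 273.15
    strd = (p["sky_emis"] + 0.1 * (1 - cloud)) * _SIGMA * tk**4
    str_net = strd - 0.97 * _SIGMA * tk**4

    wind_u = p["wind_mean"] * 0.8 + _ar1(rng, shape, rho=0.9, sd=p["wind_sd"])
    wind_v = p["wind_mean"] * 0.4 + _ar1(rng, shape, rho=0.9, sd=p["wind_sd"] * 0.8)

    sp = 101325.0 * np.exp(-p["elev"] / 8434.0) + _ar1(rng, shape, rho=0.98, sd=120.0)

    data = {
        "t2m": (t_air + 273.15, "K"),
        "d2m": (t_dew + 273.15, "K"),
        "sp": (sp, "Pa"),
        "u10": (wind_u, "m s**-1"),
        "v10": (wind_v, "m s**-1"),
    }
    rad = {"ssrd": ssrd, "ssr": ssr, "strd": strd, "str_net": str_net, "fdir": fdir}

    # injected missingness: ocean cells and random hour-holes per cell-day
    mask = np.zeros(shape, dtype=bool)
    for r, c in cfg.ocean_cells:
        mask[:, r, c] = True
    if cfg.hole_fraction > 0:
        n_days = nt // 24
        for d in range(n_days):
            for r in range(ny):
                for c in range(nx):
                    if rng.random() < cfg.hole_fraction:
                        k = rng.integers(1, cfg.hole_hours_max + 1)
                        hrs = rng.choice(24, size=k, replace=False)
                        mask[d * 24 + hrs, r, c] = True

    ds = xr.Dataset(coords={"time": times, "lat": lats, "lon": lons})
    for name, (arr, units) in data.items():
        arr = np.where(mask, np.nan, arr)
        ds[name] = (("time", "lat", "lon"), arr, {"units": units})
    day_index = np.arange(nt) // 24
    for name, flux in rad.items():
        flux = np.where(mask, np.nan, flux)
        acc = np.zeros_like(flux)
        for d in np.unique(day_index):
            sel = day_index == d
            acc[sel] = np.nancumsum(flux[sel] * 3600.0, axis=0)
            acc[sel] = np.where(np.isnan(flux[sel]), np.nan, acc[sel])
        ds[name] = (("time", "lat", "lon"), acc, {"units": "J m**-2"})
    ds.attrs["preset"] = cfg.preset
    ds.attrs["seed"] = cfg.seed
    return ds


def gen_land_cover(cfg: SynthConfig) -> pd.DataFrame:
    """Fraction-developed per cell (long table row, col, fraction)."""
    rng = np.random.default_rng(cfg.seed + 1)
    frac = np.clip(rng.beta(1.2, 3.0, size=(cfg.n_lat, cfg.n_lon)), 0.0, 1.0)
    rows, cols = np.meshgrid(np.arange(cfg.n_lat), np.arange(cfg.n_lon), indexing="ij")
    return pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(),
                         "fraction_developed": frac.ravel()})


def gen_offsets(cfg: SynthConfig) -> OffsetSchedule:
    """Two-zone offset maps split at a longitude, optionally re-zoned.

    With ``tz_change_year`` set, a central stripe of cells moves from the
    western to the eastern zone starting that year — the mechanism used for
    mid-record time-zone changes.
    """
    west = cfg.lons < cfg.tz_boundary_lon
    lst = np.where(west[None, :], cfg.tz_west_offset, cfg.tz_east_offset)
    lst = np.broadcast_to(lst, (cfg.n_lat, cfg.n_lon)).copy()
    ldt = lst + 1 if cfg.dst else lst
    if cfg.tz_change_year is None:
        periods = [(1900, 2099, lst, ldt)]
    else:
        lst2 = lst.copy()
        stripe = np.argmin(np.abs(cfg.lons - cfg.tz_boundary_lon))
        lst2[:, max(stripe - 1, 0):stripe + 1] = cfg.tz_east_offset
        ldt2 = lst2 + 1 if cfg.dst else lst2
        periods = [(1900, cfg.tz_change_year - 1, lst, ldt),
                   (cfg.tz_change_year, 2099, lst2, ldt2)]
    return OffsetSchedule(periods=periods, use_dst=cfg.dst)


def gen_counties(cfg: SynthConfig):
    """Toy counties and population points for both epochs.

    Counties are vertical slabs spanning the grid north–south, so with the
    default half-grid time-zone boundary at least one county straddles both
    zones.  Returns ``(counties, {epoch: points})`` where points hold
    (lon, lat, pop) rows summing to the configured county populations.
    """
    if cfg.n_counties < 2:
        raise ValueError("need at least two counties")
    lat_lo = cfg.lat0 - cfg.dlat / 2
    lat_hi = cfg.lat0 + cfg.dlat * (cfg.n_lat - 0.5)
    lon_edges = np.linspace(cfg.lon0 - cfg.dlon / 2,
                            cfg.lon0 + cfg.dlon * (cfg.n_lon - 0.5),
                            cfg.n_counties + 1)
    counties = [
        CountyRectangle(fips=f"{1 + 2*i:02d}{(13 + 2*i):03d}",
                        lon_min=lon_edges[i], lon_max=lon_edges[i + 1],
                        lat_min=lat_lo, lat_max=lat_hi)
        for i in range(cfg.n_counties)
    ]
    pops = list(cfg.populations)
    if len(pops) < cfg.n_counties:
        pops = (pops * cfg.n_counties)[:cfg.n_counties]

    points = {}
    for e, epoch in enumerate(("2000", "2015")):
        rng = np.random.default_rng(cfg.seed + 10 + e)
        rows = []
        for county, pop in zip(counties, pops):
            n_pts = 40
            lon = rng.uniform(county.lon_min, county.lon_max, n_pts)
            lat = rng.uniform(county.lat_min, county.lat_max, n_pts)
            raw = rng.integers(1, 50, n_pts).astype(float)
            counts = np.floor(raw / raw.sum() * pop).astype(int)
            counts[0] += pop - counts.sum()
            for x, y, c in zip(lon, lat, counts):
                if c > 0:
                    rows.append((x, y, int(c)))
        points[epoch] = pd.DataFrame(rows, columns=["lon", "lat", "pop"])
    return counties, points


def write_fixture(cfg: SynthConfig, outdir):
    """Write the complete fixture (NetCDF + CSVs + pipeline config) to a dir."""
    import pathlib

    import yaml

    from .county import build_weights

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = gen_meteo(cfg)
    ds.to_netcdf(out / "meteo.nc", engine="scipy")
    gen_land_cover(cfg).to_csv(out / "land_cover.csv", index=False)

    schedule = gen_offsets(cfg)
    rows = []
    for y0, y1, lst, ldt in schedule.periods:
        for r in range(cfg.n_lat):
            for c in range(cfg.n_lon):
                rows.append((y0, y1, r, c, int(lst[r, c]), int(ldt[r, c])))
    pd.DataFrame(rows, columns=["year_from", "year_to", "row", "col", "lst", "ldt"]) \
        .to_csv(out / "offsets.csv", index=False)

    counties, points = gen_counties(cfg)
    pd.DataFrame([asdict(c) for c in counties]).to_csv(out / "counties.csv", index=False)
    weights = []
    for epoch, pts in points.items():
        pts.to_csv(out / f"population_{epoch}.csv", index=False)
        weights.append(build_weights(pts, counties, cfg.lats, cfg.lons, epoch))
    pd.concat(weights).to_csv(out / "weights.csv", index=False)

    pipeline_cfg = {
        "meteo": "meteo.nc",
        "land_cover": "land_cover.csv",
        "offsets": "offsets.csv",
        "weights": "weights.csv",
        "output": "county_days.csv",
        "report": "report.json",
        "wbgt_variant": "modified",
        "use_dst": cfg.dst,
        "epoch_boundary": 2010,
        "epochs": ["2000", "2015"],
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh)
    with open(out / "fixture_meta.yaml", "w") as fh:
        yaml.safe_dump({"seed": cfg.seed, "preset": cfg.preset,
                        "config": {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in asdict(cfg).items()}}, fh)
    return out
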