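"""End-to-end orchestration: ingest, metric computation, aggregation, output.

The pipeline reads hourly gridded meteorology (NetCDF, CF-style units
attributes), normalizes units exactly once (Kelvin → °C, Pa → hPa,
accumulated J/m² → hourly-mean W/m²), computes the seven hourly metric
families (T, TD, NET, HI, HX, WBGT, UTCI), aggregates to local calendar
days through per-cell UTC-offset maps, population-weights to counties, and
writes the published table schema as CSV alongside a JSON run report with
per-stage counts (flags, clamp/cap events, solver non-convergence).
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import county as county_mod
from . import indices, psychro, solar, temporal, utci, wbgt

__all__ = ["PipelineConfig", "run_pipeline", "compute_hourly_metrics"]

log = logging.getLogger(__name__)

_REQUIRED_VARS = ("t2m", "d2m", "sp", "u10", "v10",
                  "ssrd", "ssr", "strd", "str_net", "fdir")
_RADIATION = ("ssrd", "ssr", "strd", "str_net", "fdir")


@dataclass
class PipelineConfig:
    """Run configuration; paths are resolved relative to ``base_dir``."""

    meteo: str
    land_cover: str
    offsets: str
    weights: str
    output: str
    report: str | None = None
    variables: dict = field(default_factory=dict)   # canonical -> file name
    wbgt_variant: str = "modified"
    use_dst: bool = True
    epoch_boundary: int = 2010
    epochs: tuple = ("2000", "2015")
    weighted: bool = True
    tidy: bool = False
    keep_missing_counties: bool = False
    min_hours: int = temporal.MIN_HOURS_PER_DAY
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path):
        path = pathlib.Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.setdefault("base_dir", str(path.parent))
        if "epochs" in raw:
            raw["epochs"] = tuple(raw["epochs"])
        return cls(**raw)

    def path(self, name):
        return pathlib.Path(self.base_dir) / getattr(self, name)


def _normalize_units(ds: xr.Dataset, name_map) -> xr.Dataset:
    """Map variable names and convert to canonical units exactly once.

    Canonical: temperatures °C, pressure hPa, radiation W/m², wind m/s.
    Declared units are cross-checked against the data's magnitude so that
    feeding pre-converted data fails loudly instead of converting twice.
    """
    out = xr.Dataset(coords=ds.coords)
    for canon in _REQUIRED_VARS:
        src = name_map.get(canon, canon)
        if src not in ds:
            raise ValueError(f"required variable {canon!r} (file name {src!r}) missing")
        da = ds[src]
        units = str(da.attrs.get("units", "")).strip()
        vals = da.values.astype(float)
        finite = vals[np.isfinite(vals)]
        if canon in ("t2m", "d2m"):
            if units in ("K", "kelvin", ""):
                if finite.size and finite.min() < 150.0:
                    raise ValueError(f"{canon}: declared Kelvin but values look "
                                     "already converted to °C (double conversion?)")
                vals = vals - 273.15
            elif units in ("degC", "C", "celsius"):
                if finite.size and finite.max() > 150.0:
                    raise ValueError(f"{canon}: declared °C but values look like Kelvin")
            else:
                raise ValueError(f"{canon}: unresolved units {units!r}")
        elif canon == "sp":
            if units in ("Pa", "pa", ""):
                if finite.size and finite.max() < 20000.0:
                    raise ValueError("sp: declared Pa but values look like hPa")
                vals = vals / 100.0
            elif units in ("hPa", "mb", "millibar"):
                if finite.size and finite.max() > 20000.0:
                    raise ValueError("sp: declared hPa but values look like Pa")
            else:
                raise ValueError(f"sp: unresolved units {units!r}")
        elif canon in _RADIATION:
            if units in ("J m**-2", "J/m2", "J m-2"):
                vals = temporal.deaccumulate(vals, window=24, axis=0,
                                             allow_negative=(canon == "str_net"))
            elif units in ("W m**-2", "W/m2", "W m-2"):
                pass
            else:
                raise ValueError(f"{canon}: unresolved units {units!r}")
        out[canon] = (da.dims, vals)
    return out


def compute_hourly_metrics(met: xr.Dataset, urban_flag, variant="modified"):
    """The seven hourly metric fields from unit-normalized meteorology.

    Returns ``(dict of family -> ndarray (time, lat, lon), report dict)``.
    """
    times = met["time"].values
    lats = met["lat"].values
    lons = met["lon"].values
    t_air = met["t2m"].values
    t_dew = met["d2m"].values
    p_hpa = met["sp"].values

    speed10 = psychro.apply_wind_floor(
        psychro.wind_magnitude(met["u10"].values, met["v10"].values))
    speed10 = np.where(np.isfinite(met["u10"].values), speed10, np.nan)
    rh = psychro.relative_humidity(t_air, t_dew)

    nt = len(times)
    lat3 = np.broadcast_to(lats[None, :, None], t_air.shape)
    lon3 = np.broadcast_to(lons[None, None, :], t_air.shape)
    time3 = np.broadcast_to(np.asarray(times)[:, None, None], t_air.shape)
    cza_dm = solar.daytime_mean_cza(lat3, lon3, time3)
    dist = solar.solar_position(0.0, 0.0, times).sun_earth_distance_au
    dist3 = np.broadcast_to(np.asarray(dist)[:, None, None], t_air.shape)

    metrics = {"T": t_air, "TD": t_dew}
    metrics["NET"] = indices.net_effective_temperature(t_air, rh, speed10)
    metrics["HI"] = indices.heat_index_nws(t_air, t_dew)
    metrics["HX"] = indices.humidex(t_air, t_dew)

    winp = wbgt.WbgtInput(
        air=psychro.AirState(t_air=t_air, t_dew=t_dew, p_air=p_hpa),
        speed10=speed10, solar=met["ssrd"].values, cza_daytime_mean=cza_dm,
        urban=np.broadcast_to(np.asarray(urban_flag)[None, :, :], t_air.shape),
        sun_earth_distance=dist3,
    )
    comp = wbgt.wbgt(winp, variant=variant)
    metrics["WBGT"] = comp.wbgt

    rad = utci.RadiationSet(
        ssrd=met["ssrd"].values, ssr=met["ssr"].values, strd=met["strd"].values,
        str_net=met["str_net"].values, fdir=met["fdir"].values,
        cza_daytime_mean=cza_dm,
    )
    t_mrt = utci.mean_radiant_temperature(rad)
    utci_vals, clamped = utci.utci_from_fields(t_air, t_dew, speed10, t_mrt)
    metrics["UTCI"] = utci_vals

    report = {
        "hours": int(nt),
        "cells": int(t_air.shape[1] * t_air.shape[2]),
        "wbgt_solar_capped": comp.diagnostics["n_solar_capped"],
        "wbgt_nonconverged": comp.diagnostics["n_nonconverged_w"]
        + comp.diagnostics["n_nonconverged_g"],
        "utci_rh_clamped_hours": int(np.count_nonzero(clamped & np.isfinite(t_air))),
        "utci_wind_capped_hours": int(np.count_nonzero(
            np.isfinite(speed10) & (speed10 > utci.WIND_CAP_MS))),
    }
    return metrics, report


def _load_offsets(path, n_lat, n_lon, use_dst):
    df = pd.read_csv(path)
    periods = []
    for (y0, y1), grp in df.groupby(["year_from", "year_to"], sort=True):
        lst = np.zeros((n_lat, n_lon), dtype=int)
        ldt = np.zeros((n_lat, n_lon), dtype=int)
        lst[grp["row"], grp["col"]] = grp["lst"]
        ldt[grp["row"], grp["col"]] = grp["ldt"]
        periods.append((int(y0), int(y1), lst, ldt))
    return temporal.OffsetSchedule(periods=periods, use_dst=use_dst)


def run_pipeline(cfg: PipelineConfig):
    """Execute the full pipeline; returns ``(records, report)``.

    Writes the county-day CSV (published schema, or a long/tidy layout when
    configured) and, if requested, a JSON run report.
    """
    ds = xr.open_dataset(cfg.path("meteo"))
    met = _normalize_units(ds, cfg.variables)
    lc = pd.read_csv(cfg.path("land_cover"))
    n_lat, n_lon = met["lat"].size, met["lon"].size
    frac = np.zeros((n_lat, n_lon))
    frac[lc["row"], lc["col"]] = lc["fraction_developed"]
    urban = wbgt.classify_urban(frac)

    metrics, report = compute_hourly_metrics(met, urban, variant=cfg.wbgt_variant)

    schedule = _load_offsets(cfg.path("offsets"), n_lat, n_lon, cfg.use_dst)
    daily = {}
    incomplete = set()
    for fam, vals in metrics.items():
        stats = temporal.daily_stats(vals, met["time"].values, schedule,
                                     min_hours=cfg.min_hours)
        daily[fam] = stats
        incomplete.update(stats.attrs["incomplete_days"])
    report["incomplete_local_days"] = sorted(incomplete)

    weights = pd.read_csv(cfg.path("weights"), dtype={"fips": str})
    weights["fips"] = weights["fips"].str.zfill(5)
    weights["epoch"] = weights["epoch"].astype(str)
    records = county_mod.assemble_records(
        daily, weights, epoch_boundary=cfg.epoch_boundary, epochs=tuple(cfg.epochs),
        weighted=cfg.weighted, drop_all_missing=not cfg.keep_missing_counties,
    )

    flag_counts = {}
    for fam in county_mod.METRIC_FAMILIES:
        counts = records[f"Flag_{fam}"].value_counts().to_dict()
        flag_counts[fam] = {int(k): int(v) for k, v in sorted(counts.items())}
    report["county_days"] = int(len(records))
    report["flag_counts"] = flag_counts
    n_flagged = int((records[[f"Flag_{f}" for f in county_mod.METRIC_FAMILIES]] != 0)
                    .any(axis=1).sum())
    report["unflagged_fraction"] = (
        1.0 - n_flagged / len(records) if len(records) else float("nan"))

    out_path = cfg.path("output")
    if cfg.tidy:
        tidy = records.melt(id_vars=["StCoFIPS", "Date"],
                            var_name="variable", value_name="value")
        tidy.to_csv(out_path, index=False)
    else:
        records.to_csv(out_path, index=False)
    if cfg.report:
        with open(cfg.path("report"), "w") as fh:
            json.dump(report, fh, indent=2)
    log.info("pipeline complete: %d county-days, %.2f%% unflagged",
             report["county_days"], 100 * report.get("unflagged_fraction", float("nan")))
    return records, report
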