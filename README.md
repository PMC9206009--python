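# heatstack

Heat-stress metrics for population-health research, computed from hourly
gridded meteorology and delivered as daily, population-weighted county
summaries.

Epidemiologic studies of heat increasingly need exposure metrics richer
than ambient temperature — wet-bulb globe temperature (WBGT) and the
Universal Thermal Climate Index (UTCI) fold in humidity, solar radiation
and wind, but computing them from reanalysis fields takes geoscientific
plumbing most health researchers should not have to build.  `heatstack`
implements that pipeline: seven hourly metric families on a lat/lon grid,
aligned to each cell's *local* calendar day through UTC-offset maps, then
averaged over counties with population weights and ordinal coverage flags.

## Metrics

| Family | Definition |
|---|---|
| `T`, `TD` | 2 m ambient and dew-point temperature, °C |
| `NET` | net effective temperature, 37 − (37−T)/(0.68 − 0.0014·RH + 1/(1.76 + 1.4·w^0.75)) − 0.29·T·(1 − RH/100) |
| `HI` | heat index (operational simple/Rothfusz scheme with low- and high-RH adjustments) |
| `HX` | humidex, T + (5/9)(e − 10) with e in hPa |
| `WBGT` | 0.70·T_w + 0.20·T_g + 0.10·T_a, with the natural wet-bulb temperature T_w and globe temperature T_g solved from physical energy balances (Liljegren model) |
| `UTCI` | 6th-order polynomial approximation in T_a, wind, vapor pressure and mean radiant temperature (MRT from six radiation fluxes) |

The WBGT solver carries a `modified`/`original` variant switch covering
four algorithm refinements (pressure-dependent saturation enhancement
factor, corrected night stability classes, corresponding-states latent
heat, 0.5 m/s wind floor) so their joint impact can be quantified.
Operational guards: wind is floored at 0.5 m/s everywhere, UTCI is marked
missing above 17 m/s, and vapor pressure is clamped to 5% relative
humidity, the polynomial's validated lower bound.

Daily statistics follow the local clock per cell (standard/daylight-time
offset rasters with validity periods for mid-record time-zone changes); a
county-day metric is missing below 21 hourly values, and each value carries
a flag: 0 (≥50% of county population represented), 1 (10–49%), 2 (<10%),
3 (missing).

## Worked example

Generate a synthetic fixture (4×4 grid, 5 July days, three counties across
two time zones) and run the pipeline:

```sh
$ heatstack synth --preset summer-humid --seed 7 --days 5 --nlat 4 --nlon 4 --out demo
fixture written to demo
$ heatstack compute --config demo/config.yaml
12 county-day rows -> demo/county_days.csv
  utci_rh_clamped_hours: 0
  utci_wind_capped_hours: 0
  wbgt_nonconverged: 0
  unflagged_fraction: 1.0
```

The output CSV has one row per county per local day — 2 key columns,
21 metric columns (min/max/mean per family), 7 flag columns:

```text
StCoFIPS,Date,Tmin_C,Tmax_C,Tmean_C,...,UTCImean_C,Flag_T,...,Flag_UTCI
01013,20200701,18.98,31.48,25.36,...
```

Here county `01013` saw a 31.5 °C maximum temperature on 2020-07-01;
every flag is 0 because the fixture is complete and each county's full
population is represented.  `heatstack weights` builds the population
weight tables from point-population and county files; the fixture's
meteorology is NetCDF with CF-style units (`K`, `Pa`, accumulated
`J m**-2` radiation), and ingest normalizes units exactly once, failing
loudly on pre-converted data.

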