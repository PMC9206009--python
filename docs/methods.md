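# Methods

This note documents the models, the numerical choices, and what the
synthetic test conditions do and do not establish.

## Psychrometrics

Two vapor-pressure formulations coexist deliberately. Reported relative
humidity and the simple indices use the Lawrence (2005) form in °C
(e = 610.94·exp(17.625·T/(243.04+T)) Pa; humidex uses the hPa-scaled
constant 6.1094, numerically identical to 610.94/100). The energy-balance
solvers use the Buck form in Kelvin,
e_s = 6.1121·exp(17.502·(T−273.15)/(T−32.18)) hPa, multiplied by a
moist-air enhancement factor. The published typeset of that factor reads as
a product ("1.0007·3.46·10⁻⁶·P"); this is a transcription artifact of the
Buck (1981) Eq. 8 sum 1.0007 + 3.46·10⁻⁶·P (hPa), which is what we
implement. The `original` algorithm variant instead uses the constant 1.004
factor, valid only above ~800 hPa — the motivation for the
pressure-dependent replacement is high-elevation grid cells.

Latent heat of vaporization uses a generalized corresponding-states
(Watson-type) scaling with water's critical temperature,
L(T) = 2.4073·10⁶·((1 − T/647.096 K)/(1 − 313.15/647.096))^0.38 J/kg,
anchored at 40 °C where it coincides with the original algorithm's linear
formula L(T) = 2.4073·10⁶ − 71100·(T − 313.15)/30. Both agree with
steam-table values within 1% over 250–350 K; the swap moves wet-bulb
estimates by well under 0.1 °C.

All wind-consuming metrics receive the 10 m speed √(u²+v²) floored at
0.5 m/s as a pre-processing step. Very low reanalysis winds otherwise
produce unreasonably high wet-bulb globe temperatures; 0.5 m/s is a
compromise between the instrument-level 0.13 m/s minimum and the 1 m/s
apparent wind of a moving person, appropriate for a database not limited to
outdoor workers.

## Solar geometry

Solar position is the NOAA/Meeus ephemeris (declination, equation of time,
hour angle), accurate to well under 0.1° zenith over 1950–2050 — far inside
the ~0.5° the heat metrics need. The cosine of the solar zenith angle that
feeds both the WBGT solver and MRT is the *daytime mean* over the hour
**ending** at the field timestamp (the accumulation convention of
reanalysis radiation): 60 evenly spaced subsamples, averaged over only the
sunlit subsamples, zero if the hour is fully dark. Normalizing direct-beam
irradiance by this quantity avoids the large sunrise/sunset errors of an
instantaneous cosine; the integration choice itself moves UTCI by well
under 0.01 °C, so 60 subsamples (vs. a brute-force 600, tested to 10⁻³) is
ample. Whether the averaging interval is centered on or ends at the
timestamp is not externally specified; ending it there matches
accumulation-style fields and is asserted throughout.

## Wet-bulb globe temperature

T_w and T_g solve wetted-wick and globe energy balances with standard
geometry (globe diameter 0.0508 m; wick 0.007 m × 0.0254 m), Chapman–Enskog
transport properties, a sphere/cylinder Nusselt-number convection law, sky
emissivity 0.575·e^0.143, and surface albedo 0.45. Measured irradiance is
capped at 0.85 of the top-of-atmosphere value for the current sun-earth
distance (a guard that also disarms abusive synthetic inputs; capped cells
are counted and logged, never silently altered), and the direct fraction
follows the clear-sky-ratio correlation f_dir = exp(3 − 1.34·s − 1.65/s)
clamped to [0, 0.9]. The separately supplied direct-beam field is used only
by the MRT/UTCI path.

Wind is converted 10 m → 2 m by a stability-class power law
(v₂ = v₁₀·(2/10)^p) with EPA urban/rural exponents per Pasquill class;
cells are urban when ≥33% of their land-cover pixels are developed.
Daytime classes come from wind × insolation (bins at 925/675/175 W/m²);
night classes from wind × the sign of the fixed 2 m−10 m temperature
difference of −0.052 °C (a −6.5 °C/km lapse over the 8 m gap). The
`modified` variant uses the corrected D/E entries for night winds in
[2.0, 2.5) m/s (the half-open interval matching the adjacent ≥2.5 m/s
row); `original` restores the E/F entries. After conversion the speed is
re-floored (0.5 m/s modified, 0.13 m/s original) because the power law can
push an already-floored speed back below the minimum.

Both solvers use damped fixed-point iteration (new = 0.9·prev + 0.1·step),
tolerance 0.02 °C, at most 50 iterations; non-convergence yields a missing
value plus a logged count, and identical inputs always produce identical
outputs. Degenerate radicands in the globe update are clipped to stay
iterable and are caught by the convergence flag.

## Mean radiant temperature and UTCI

MRT combines six radiation terms: angle-weighted longwave
(0.5·strd + 0.5·(strd − str_net)) and shortwave scaled by the body's
absorption/emissivity ratio 0.7/0.97 — 0.5·diffuse (ssrd − fdir),
0.5·ground-reflected (ssrd − ssr), and the direct beam normalized by the
daytime-mean cosine zenith angle and weighted by the projected-area
fraction f_p = 0.308·cos(γ(0.998 − γ²/50000)) of a standing person (γ =
solar elevation, degrees). A dark hour contributes exactly zero direct
radiation (no division by the zero cosine); a negative radicand — possible
only for physically inconsistent inputs — returns missing with a
diagnostic.

UTCI is the operational 210-term polynomial of total degree six in air
temperature (°C), 10 m wind (m/s), MRT−air offset (°C) and vapor pressure
(kPa). The coefficients are embedded as an exponent-tuple table frozen by a
SHA-256 checksum; the test suite carries a second transcription in the
original operational listing order and requires agreement to 0.01 °C on
random in-band states. Vapor pressure converts hPa → kPa in exactly one
place, with a unit-boundary test. Guards follow operational practice: winds
above 17 m/s (where the polynomial produces implausibly extreme values) are
marked missing rather than capped; winds below 0.5 m/s are floored
(polynomial validity starts there); vapor pressure is raised to 5% of
saturation below 5% relative humidity, the approximation's validated lower
bound. Relative humidity itself is never clipped at 100% — consumers handle
bounds.

## Heat index

The operational scheme: Steadman's simple formula
0.5·(T + 61 + (T−68)·1.2 + RH·0.094) (°F) when its average with the
temperature is below 80 °F, otherwise the Rothfusz regression with the
low-RH (RH < 13%, 80–112 °F) and high-RH (RH > 85%, 80–87 °F) adjustments;
Fahrenheit internally, °C at the boundaries. The scheme's switch is
discontinuous by construction; measurement on a dense scan shows jumps
below 0.13 °F at RH 30% rising to ~2.3 °F at RH 90%, and the tests assert
those bounds rather than pretending continuity.

## Local days and daily statistics

Radiation arrives accumulated over the UTC day (J/m²) and is differenced
back to hourly-mean W/m²; negative steps beyond tolerance are missing
(except for net thermal radiation, a legitimately signed flux). Each cell
carries integer UTC offsets for local standard and daylight time, organized
in validity periods so a cell whose zone changed mid-record uses the
period-appropriate map; DST applicability is decided on the local standard
clock with the US statutory calendar (2000–2006: first Sunday April –
last Sunday October; 2007+: second Sunday March – first Sunday November),
both at 02:00. Half-hour zones are rejected at ingest. A local day is the
24 hours 00–23 on the cell's clock; days whose UTC coverage is incomplete
are excluded and reported, never silently truncated. A cell-variable-day
with fewer than 21 non-missing hours is missing; otherwise min/max/mean are
taken over the available hours (the averaging denominator is the available
count — the flag scheme, not imputation, carries the uncertainty). Daily
extremes from hourly data can miss between-hour extremes; this is inherent
to hourly inputs and intentionally not corrected.

## County aggregation

Cell weights are the fraction of a county's population residing in the
cell, built from point-population data (a cell holding 10% of the county's
people weights 0.10); two epochs (labels "2000" and "2015", switching at
calendar year 2010) capture population shifts. County means renormalize
over non-missing cells; the summed non-missing weight is the coverage,
flagged 0 (≥0.50), 1 ([0.10, 0.50)), 2 ((0, 0.10)), 3 (exactly 0 →
missing). The half-open flag boundaries make the partition exact. Coverage
is computed per metric family per day, so the seven flags on one county-day
can differ. Zero-population counties get uniform weights over intersecting
cells with a warning; counties missing everywhere are dropped from the
output by default (configurable to all-flag-3 rows). FIPS codes are
zero-padded text throughout. An unweighted companion mode averages all
county cells equally.

## Synthetic conditions

The generator emulates reanalysis structure, not any real climate: a
sinusoidal diurnal temperature cycle peaking mid-afternoon with AR(1)
weather noise, dew points via preset depressions, solar fields consistent
with the astronomical sun (hourly means of the cosine zenith angle, direct
≤ total, net = 0.8·downward), longwave from an effective sky temperature,
AR(1) winds, and pressure from a preset elevation. Presets cover the guard
regimes: `summer-humid` (the standard 10×10-cell, 0.1°-spacing, 35-day
test grid), `desert-dry` (dew-point depressions of 38±9 °C produce genuine
sub-5%-RH hours and the 1600 m elevation exercises the pressure-dependent
enhancement factor), `coastal-windy` (gusts beyond the 17 m/s UTCI cap).
Missing-data injection covers hour-level holes (the 21-hour rule),
all-missing ocean cells (the flag-3 path), and everything derives from one
seeded generator — same config and seed, identical fixture.

What passing tests show, and what they do not: the fixture validates
plumbing, guards, invariants and the relative behavior of algorithm
variants under controlled conditions; it does not validate climatological
realism. In particular, its single-climate domain has far less spatial
variance than a continental dataset, so correlation-type comparisons
(e.g. between WBGT algorithm variants) are structurally tighter-bounded
than on real data even when absolute differences are small: on the standard
summer fixture the two variants' daily maxima differ by 0.02 °C on average
(σ ≈ 0.09 °C, driven almost entirely by the wind-floor change at calm
sunny hours), which against the fixture's ~1.5 °C daily-max spread yields
r² ≈ 0.997 — the same absolute agreement against a continental spread of
many degrees would read as r² > 0.999.

## Known limitations

Ice-phase saturation, frost points, indoor WBGT, clothing/activity
adjustments, UTCI stress categories, sub-hourly extremes, leap seconds and
real cartography are out of scope. The solver tolerance (0.02 °C) bounds
reproducibility of individual hourly WBGT values; county aggregation
averages that noise down. The nearest-neighbor regridder assumes regular
lat/lon grids and breaks midpoint ties toward the smaller index.
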