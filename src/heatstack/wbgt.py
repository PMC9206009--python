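"""Wet-bulb globe temperature via the Liljegren et al. (2008) physical model.

WBGT = 0.70·T_w + 0.20·T_g + 0.10·T_a, where the natural wet-bulb
temperature T_w and globe temperature T_g are solved from first-principles
heat/mass balances of a wetted wick and a blackened 15 cm sphere exposed to
sun, sky, ground and wind.  Two algorithm variants are provided:

``modified`` (default)
    * pressure-dependent Buck enhancement factor in saturation vapor
      pressure (valid below 800 hPa, i.e. high-elevation cells);
    * corrected night-time stability classes for winds in [2.0, 2.5) m/s
      (D for non-negative lapse, E for negative — per EPA Table 6-7);
    * corresponding-states latent heat of vaporization;
    * 0.5 m/s minimum wind speed after height conversion.

``original``
    the unmodified reference behavior: constant 1.004 enhancement factor,
    E/F night classes in [2.0, 2.5) m/s, linear-in-T latent heat, and a
    0.13 m/s post-conversion wind floor.

Internally the solvers work in Kelvin and hPa; the public API takes °C and
returns °C.  All computations vectorize over numpy arrays and are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .psychro import (
    AirState,
    esat_buck,
    heat_of_vaporization_linear,
    heat_of_vaporization_meyra,
    relative_humidity,
)

__all__ = [
    "WbgtInput",
    "WbgtComponents",
    "LAPSE_C",
    "classify_urban",
    "stability_class",
    "wind_to_2m",
    "globe_temperature",
    "natural_wet_bulb",
    "wbgt",
]

log = logging.getLogger(__name__)

#: 2 m→10 m vertical temperature difference implied by a −6.5 °C/km lapse
#: rate over the 8 m height gap, °C.
LAPSE_C = -6.5e-3 * 8.0

#: Fraction-developed threshold at or above which a cell counts as urban.
URBAN_THRESHOLD = 0.33

# --- physical constants (SI unless noted) -----------------------------------
_CP = 1003.5                      # specific heat of dry air, J/(kg K)
_M_AIR = 28.97
_M_H2O = 18.015
_R_GAS = 8314.34
_R_AIR = _R_GAS / _M_AIR
_PR = _CP / (_CP + 1.25 * _R_AIR)         # Prandtl number of air
_RATIO = _CP * _M_AIR / _M_H2O
_STEFANB = 5.6696e-8

_EMIS_WICK, _ALB_WICK = 0.95, 0.4
_DIAM_WICK, _LEN_WICK = 0.007, 0.0254     # m
_EMIS_GLOBE, _ALB_GLOBE = 0.95, 0.05
_DIAM_GLOBE = 0.0508                      # m
_EMIS_SFC, _ALB_SFC = 0.999, 0.45

_SOLAR_CONST = 1367.0
#: Minimum cosine zenith treated as daytime (sun ~0.5° above horizon).
CZA_MIN = 0.00873
#: Maximum allowed ratio of measured to top-of-atmosphere irradiance.
NORMSOLAR_MAX = 0.85

CONVERGENCE = 0.02   # K, solver tolerance
MAX_ITER = 50

_WIND_FLOOR = {"modified": 0.5, "original": 0.13}

# EPA SRDT daytime stability table: rows are 10 m wind-speed bins
# [<2, 2–3, 3–5, 5–6, >=6) m/s, columns insolation bins
# [>=925, 675–925, 175–675, <175) W/m²; entries are classes 1..6 = A..F.
_DAY_TABLE = np.array([
    [1, 1, 2, 4],
    [1, 2, 3, 4],
    [2, 2, 3, 4],
    [3, 3, 4, 4],
    [3, 4, 4, 4],
])

# Night rows [<2.0, 2.0–2.5, >=2.5) m/s × lapse sign (dT>=0, dT<0).
_NIGHT_TABLE = {
    "modified": np.array([[5, 6], [4, 5], [4, 5]]),
    "original": np.array([[5, 6], [5, 6], [4, 5]]),
}

# Wind-profile power-law exponents per stability class A..F.
_EXP_URBAN = np.array([0.15, 0.15, 0.20, 0.25, 0.30, 0.30])
_EXP_RURAL = np.array([0.07, 0.07, 0.10, 0.15, 0.35, 0.55])


@dataclass
class WbgtInput:
    """Inputs to one (vectorized) WBGT evaluation.

    ``speed10`` must already carry the global 0.5 m/s floor; ``solar`` is the
    downward surface solar irradiance in W/m² and ``cza_daytime_mean`` the
    sunlit-hour mean cosine zenith angle used both to bound the irradiance
    and to split it into direct and diffuse parts.
    """

    air: AirState
    speed10: np.ndarray          # m/s, floored
    solar: np.ndarray            # W/m²
    cza_daytime_mean: np.ndarray
    urban: np.ndarray            # 0/1
    lapse: float = LAPSE_C       # °C over the 2–10 m gap
    wind_height: float = 10.0    # m
    sun_earth_distance: np.ndarray | float = 1.0   # AU


@dataclass
class WbgtComponents:
    """Solved WBGT and its components, °C."""

    t_w: np.ndarray
    t_g: np.ndarray
    t_a: np.ndarray
    wbgt: np.ndarray
    converged_w: np.ndarray
    converged_g: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def classify_urban(fraction_developed, threshold=URBAN_THRESHOLD):
    """Binary urban flag: 1 where the developed fraction is >= threshold."""
    frac = np.asarray(fraction_developed, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fraction_developed outside [0, 1]")
    out = (frac >= threshold).astype(np.int8)
    return out if out.ndim else int(out)


def stability_class(speed10, solar, cza, lapse=LAPSE_C, variant="modified"):
    """Pasquill stability class (1..6 = A..F) via the EPA SRDT scheme.

    Daytime (positive adjusted solar irradiance) classes come from wind
    speed × insolation; night classes from wind speed × the sign of the
    2 m − 10 m temperature difference.  The ``modified`` variant applies the
    corrected D/E entries for night winds in [2.0, 2.5) m/s.
    """
    speed10 = np.asarray(speed10, dtype=float)
    solar = np.asarray(solar, dtype=float)
    cza = np.asarray(cza, dtype=float)
    lapse = np.asarray(lapse, dtype=float)
    day = (solar > 0.0) & (cza > CZA_MIN)

    i_day = np.digitize(speed10, [2.0, 3.0, 5.0, 6.0])
    j_day = np.select(
        [solar >= 925.0, solar >= 675.0, solar >= 175.0], [0, 1, 2], default=3
    )
    cls_day = _DAY_TABLE[i_day, j_day]

    i_night = np.digitize(speed10, [2.0, 2.5])
    j_night = np.where(lapse >= 0.0, 0, 1)
    cls_night = _NIGHT_TABLE[variant][i_night, j_night]

    out = np.where(day, cls_day, cls_night)
    return out if out.ndim else int(out)


def wind_to_2m(speed10, stability, urban, variant="modified", wind_height=10.0):
    """Convert a 10 m wind speed to 2 m via the stability power law.

    ``speed2 = speed10 * (2 / wind_height) ** p`` with the class- and
    land-cover-specific exponent, then floored at the variant's minimum
    (0.5 m/s modified, 0.13 m/s original) — the floor is re-applied here
    because conversion can push an already-floored speed back below it.
    """
    speed10 = np.asarray(speed10, dtype=float)
    stability = np.asarray(stability)
    urban = np.asarray(urban)
    p = np.where(urban.astype(bool), _EXP_URBAN[stability - 1], _EXP_RURAL[stability - 1])
    out = np.maximum(speed10 * (2.0 / wind_height) ** p, _WIND_FLOOR[variant])
    return out if out.ndim else float(out)


# --- air transport properties (Kelvin / hPa internally) ---------------------

def _viscosity(tk):
    """Dynamic viscosity of air, kg/(m s) (Chapman–Enskog)."""
    omega = (tk / 97.0 - 2.9) / 0.4 * (-0.034) + 1.048
    return 2.6693e-6 * np.sqrt(_M_AIR * tk) / (3.617**2 * omega)


def _thermal_conductivity(tk):
    return (_CP + 1.25 * _R_AIR) * _viscosity(tk)


def _diffusivity(tk, p_hpa):
    """Binary diffusivity of water vapor in air, m²/s."""
    pcrit13 = (36.4 * 218.0) ** (1.0 / 3.0)
    tcrit512 = (132.0 * 647.3) ** (5.0 / 12.0)
    tcrit12 = (132.0 * 647.3) ** 0.5
    mmix = (1.0 / _M_AIR + 1.0 / _M_H2O) ** 0.5
    return 0.000364 * (tk / tcrit12) ** 2.334 * pcrit13 * tcrit512 * mmix / (p_hpa / 1013.25) * 1e-4


def _emis_atm(tk, rh_frac, p_hpa, variant):
    """Clear-sky atmospheric emissivity from vapor pressure, dimensionless."""
    e = rh_frac * esat_buck(tk, p_hpa, variant)
    return 0.575 * e**0.143


def _h_cylinder(tk, p_hpa, speed):
    """Convective heat-transfer coefficient of the wick cylinder, W/(m² K)."""
    density = p_hpa * 100.0 / (_R_AIR * tk)
    re = speed * density * _DIAM_WICK / _viscosity(tk)
    nu = 0.281 * re ** (1.0 - 0.4) * _PR ** (1.0 - 0.56)
    return nu * _thermal_conductivity(tk) / _DIAM_WICK


def _h_sphere(tk, p_hpa, speed):
    """Convective heat-transfer coefficient of the globe, W/(m² K)."""
    density = p_hpa * 100.0 / (_R_AIR * tk)
    re = speed * density * _DIAM_GLOBE / _viscosity(tk)
    nu = 2.0 + 0.6 * re**0.5 * _PR ** (1.0 / 3.0)
    return nu * _thermal_conductivity(tk) / _DIAM_GLOBE


def _adjust_solar(solar, cza, dist):
    """Bound irradiance by clear sky and split into a direct fraction.

    Returns (solar, fdir, n_capped).  Irradiance is capped at
    ``NORMSOLAR_MAX`` times the top-of-atmosphere value for the cell's
    cosine zenith angle; the direct-beam fraction follows the clear-sky
    ratio correlation ``fdir = exp(3 − 1.34 s − 1.65/s)`` clamped to
    [0, 0.9].  Night (cza below CZA_MIN) gives solar = fdir = 0.
    """
    solar = np.asarray(solar, dtype=float)
    cza = np.asarray(cza, dtype=float)
    toa = _SOLAR_CONST * np.maximum(cza, 0.0) / np.asarray(dist, dtype=float) ** 2
    toa = np.where(cza < CZA_MIN, 0.0, toa)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(toa > 0.0, solar / toa, 0.0)
    capped = ratio > NORMSOLAR_MAX
    ratio = np.minimum(ratio, NORMSOLAR_MAX)
    solar_adj = np.where(toa > 0.0, np.where(capped, NORMSOLAR_MAX * toa, solar), 0.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        fdir = np.where(ratio > 0.0, np.exp(3.0 - 1.34 * ratio - 1.65 / np.maximum(ratio, 1e-12)), 0.0)
    fdir = np.clip(fdir, 0.0, 0.9)
    n_capped = int(np.count_nonzero(capped))
    if n_capped:
        log.info("solar irradiance capped at clear-sky maximum in %d cells", n_capped)
    return solar_adj, fdir, n_capped


def _solve_globe(tk_air, rh_frac, p_hpa, speed2, solar, fdir, cza, variant,
                 emis_atm_override=None):
    """Fixed-point iteration for the globe temperature, K."""
    tsfc = tk_air
    ea = _emis_atm(tk_air, rh_frac, p_hpa, variant) if emis_atm_override is None else emis_atm_override
    cza_safe = np.maximum(cza, CZA_MIN)
    tg = np.array(tk_air, dtype=float, copy=True)
    converged = np.zeros(np.shape(tg), dtype=bool)
    for _ in range(MAX_ITER):
        tref = 0.5 * (tg + tk_air)
        h = _h_sphere(tref, p_hpa, speed2)
        radicand = (
            0.5 * (ea * tk_air**4 + _EMIS_SFC * tsfc**4)
            - h / (_STEFANB * _EMIS_GLOBE) * (tg - tk_air)
            + solar / (2.0 * _STEFANB * _EMIS_GLOBE) * (1.0 - _ALB_GLOBE)
            * (fdir * (1.0 / (2.0 * cza_safe) - 1.0) + 1.0 + _ALB_SFC)
        )
        tg_new = np.maximum(radicand, 1.0) ** 0.25
        newly = np.abs(tg_new - tg) < CONVERGENCE
        step = 0.9 * tg + 0.1 * tg_new
        tg = np.where(converged, tg, step)
        converged = converged | newly
        if converged.all():
            break
    return tg, converged


def _solve_wetbulb(tk_air, tk_dew, rh_frac, p_hpa, speed2, solar, fdir, cza, variant,
                   emis_atm_override=None):
    """Fixed-point iteration for the natural wet-bulb temperature, K."""
    tsfc = tk_air
    ea = _emis_atm(tk_air, rh_frac, p_hpa, variant) if emis_atm_override is None else emis_atm_override
    eair = rh_frac * esat_buck(tk_air, p_hpa, variant)
    sza = np.arccos(np.clip(cza, -1.0, 1.0))
    latent = heat_of_vaporization_meyra if variant == "modified" else heat_of_vaporization_linear
    solar_term = (1.0 - _ALB_WICK) * solar * (
        (1.0 - fdir) * (1.0 + 0.25 * _DIAM_WICK / _LEN_WICK)
        + fdir * (np.tan(sza) / np.pi + 0.25 * _DIAM_WICK / _LEN_WICK)
        + _ALB_SFC
    )
    tw = np.array(tk_dew, dtype=float, copy=True)
    converged = np.zeros(np.shape(tw), dtype=bool)
    for _ in range(MAX_ITER):
        tref = 0.5 * (tw + tk_air)
        h = _h_cylinder(tref, p_hpa, speed2)
        fatm = _STEFANB * _EMIS_WICK * (
            0.5 * (ea * tk_air**4 + _EMIS_SFC * tsfc**4) - tw**4
        ) + solar_term
        ewick = esat_buck(tw, p_hpa, variant)
        density = p_hpa * 100.0 / (_R_AIR * tref)
        sc = _viscosity(tref) / (density * _diffusivity(tref, p_hpa))
        tw_new = (
            tk_air
            - latent(tref) / _RATIO * (ewick - eair) / (p_hpa - ewick) * (_PR / sc) ** 0.56
            + fatm / h
        )
        newly = np.abs(tw_new - tw) < CONVERGENCE
        step = 0.9 * tw + 0.1 * tw_new
        tw = np.where(converged, tw, step)
        converged = converged | newly
        if converged.all():
            break
    return tw, converged


def globe_temperature(inp: WbgtInput, speed2, variant="modified", emis_atm_override=None):
    """Globe temperature, °C, for pre-converted 2 m wind speeds."""
    tk_air = np.asarray(inp.air.t_air, dtype=float) + 273.15
    rh = relative_humidity(inp.air.t_air, inp.air.t_dew) / 100.0
    solar, fdir, _ = _adjust_solar(inp.solar, inp.cza_daytime_mean, inp.sun_earth_distance)
    tg, ok = _solve_globe(tk_air, rh, np.asarray(inp.air.p_air, dtype=float), speed2,
                          solar, fdir, inp.cza_daytime_mean, variant, emis_atm_override)
    return np.where(ok, tg - 273.15, np.nan)


def natural_wet_bulb(inp: WbgtInput, speed2, variant="modified", emis_atm_override=None):
    """Natural wet-bulb temperature, °C, for pre-converted 2 m wind speeds."""
    tk_air = np.asarray(inp.air.t_air, dtype=float) + 273.15
    tk_dew = np.asarray(inp.air.t_dew, dtype=float) + 273.15
    rh = relative_humidity(inp.air.t_air, inp.air.t_dew) / 100.0
    solar, fdir, _ = _adjust_solar(inp.solar, inp.cza_daytime_mean, inp.sun_earth_distance)
    tw, ok = _solve_wetbulb(tk_air, tk_dew, rh, np.asarray(inp.air.p_air, dtype=float),
                            speed2, solar, fdir, inp.cza_daytime_mean, variant,
                            emis_atm_override)
    return np.where(ok, tw - 273.15, np.nan)


def wbgt(inp: WbgtInput, variant="modified") -> WbgtComponents:
    """Solve the full WBGT = 0.70·T_w + 0.20·T_g + 0.10·T_a, °C.

    The 10 m wind is converted to 2 m through the stability-class power law
    before entering both solvers.  Non-converged components propagate NaN.
    """
    if variant not in _WIND_FLOOR:
        raise ValueError(f"unknown variant {variant!r}")
    t_air = np.asarray(inp.air.t_air, dtype=float)
    tk_air = t_air + 273.15
    tk_dew = np.asarray(inp.air.t_dew, dtype=float) + 273.15
    p_hpa = np.asarray(inp.air.p_air, dtype=float)
    rh = relative_humidity(inp.air.t_air, inp.air.t_dew) / 100.0

    solar, fdir, n_capped = _adjust_solar(inp.solar, inp.cza_daytime_mean,
                                          inp.sun_earth_distance)
    cls = stability_class(inp.speed10, solar, inp.cza_daytime_mean, inp.lapse, variant)
    speed2 = wind_to_2m(inp.speed10, cls, inp.urban, variant, inp.wind_height)

    tg, ok_g = _solve_globe(tk_air, rh, p_hpa, speed2, solar, fdir,
                            inp.cza_daytime_mean, variant)
    tw, ok_w = _solve_wetbulb(tk_air, tk_dew, rh, p_hpa, speed2, solar, fdir,
                              inp.cza_daytime_mean, variant)

    n_bad_w = int(np.count_nonzero(~ok_w & np.isfinite(tk_air)))
    n_bad_g = int(np.count_nonzero(~ok_g & np.isfinite(tk_air)))
    if n_bad_w or n_bad_g:
        log.warning("WBGT solver non-convergence: wet bulb %d, globe %d", n_bad_w, n_bad_g)

    t_w = np.where(ok_w, tw - 273.15, np.nan)
    t_g = np.where(ok_g, tg - 273.15, np.nan)
    value = 0.70 * t_w + 0.20 * t_g + 0.10 * t_air
    return WbgtComponents(
        t_w=t_w, t_g=t_g, t_a=t_air, wbgt=value,
        converged_w=ok_w, converged_g=ok_g,
        diagnostics={"n_solar_capped": n_capped,
                     "n_nonconverged_w": n_bad_w,
                     "n_nonconverged_g": n_bad_g},
    )
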