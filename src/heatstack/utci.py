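"""Universal Thermal Climate Index: mean radiant temperature + polynomial.

The mean radiant temperature (MRT) follows the radiation-flux approach used
operationally with reanalysis fields: a person exchanges longwave radiation
with the sky and ground (angle factors 0.5 each) and absorbs diffuse,
ground-reflected, and direct shortwave radiation, the latter weighted by the
solar-elevation-dependent projected-area fraction of the human body.  UTCI
itself is the 6th-order polynomial regression approximation of the
Fiala-model equivalent temperature, in air temperature, wind speed, the
MRT−air offset, and vapor pressure.

Operational guards applied by :func:`utci_from_fields`:

* wind speeds above 17 m/s → output marked missing (NaN);
* wind speeds below 0.5 m/s → floored (polynomial validity bound);
* relative humidity below 5% → vapor pressure clamped to 5% of saturation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .psychro import vapor_pressure_lawrence
from .utci_coeffs import UTCI_COEFFS

__all__ = [
    "RadiationSet",
    "UtciInput",
    "SIGMA_SB",
    "WIND_CAP_MS",
    "mean_radiant_temperature",
    "projected_fraction",
    "utci_polynomial",
    "utci_from_fields",
]

log = logging.getLogger(__name__)

SIGMA_SB = 5.67e-8            # Stefan-Boltzmann constant, W/(m² K⁴)
_ALPHA_SW = 0.7               # shortwave absorption coefficient of the body
_EMIS_LW = 0.97               # longwave emissivity of the body
WIND_CAP_MS = 17.0            # above this 10 m speed UTCI is marked missing
_WIND_FLOOR = 0.5
_RH_CLAMP = 0.05              # minimum relative humidity fraction


@dataclass
class RadiationSet:
    """The six radiation quantities feeding the MRT estimate, W/m².

    ``ssrd``/``ssr`` are downward and net surface solar radiation,
    ``strd``/``str_net`` downward and net surface thermal radiation, and
    ``fdir`` the direct-beam solar radiation at the surface;
    ``cza_daytime_mean`` is the sunlit-hour mean cosine zenith angle.
    """

    ssrd: np.ndarray
    ssr: np.ndarray
    strd: np.ndarray
    str_net: np.ndarray
    fdir: np.ndarray
    cza_daytime_mean: np.ndarray


@dataclass
class UtciInput:
    t_air: np.ndarray            # °C
    speed10: np.ndarray          # m/s
    vapor_pressure: np.ndarray   # hPa
    t_mrt: np.ndarray            # °C


def projected_fraction(elevation_deg):
    """Projected-area fraction of a standing body vs. solar elevation.

    ``f_p = 0.308 * cos(γ·(0.998 − γ²/50000))`` with γ the solar elevation
    in degrees (cosine argument also in degrees): 0.308 for grazing sun,
    falling to ~0.08 for overhead sun.
    """
    gamma = np.asarray(elevation_deg, dtype=float)
    arg = gamma * (0.998 - gamma**2 / 50000.0)
    out = 0.308 * np.cos(np.radians(arg))
    return out if out.ndim else float(out)


def mean_radiant_temperature(rad: RadiationSet):
    """Mean radiant temperature, °C, from the six radiation terms.

    Longwave: 0.5·strd + 0.5·upwelling with upwelling = strd − str_net.
    Shortwave (scaled by α/ε): 0.5·diffuse + 0.5·reflected + f_p·direct
    normal, where diffuse = ssrd − fdir, reflected = ssrd − ssr, and
    direct normal = fdir / cza_daytime_mean (0 when the hour is dark).
    A negative radicand (possible only for inconsistent inputs) yields NaN
    with a logged diagnostic.
    """
    ssrd = np.asarray(rad.ssrd, dtype=float)
    ssr = np.asarray(rad.ssr, dtype=float)
    strd = np.asarray(rad.strd, dtype=float)
    str_net = np.asarray(rad.str_net, dtype=float)
    fdir = np.asarray(rad.fdir, dtype=float)
    cza = np.asarray(rad.cza_daytime_mean, dtype=float)

    lw_up = strd - str_net
    sw_diffuse = ssrd - fdir
    sw_reflected = ssrd - ssr
    with np.errstate(divide="ignore", invalid="ignore"):
        direct_normal = np.where(cza > 0.0, fdir / np.maximum(cza, 1e-12), 0.0)
    gamma = np.degrees(np.arcsin(np.clip(cza, 0.0, 1.0)))
    fp = projected_fraction(gamma)

    radicand = (1.0 / SIGMA_SB) * (
        0.5 * strd + 0.5 * lw_up
        + (_ALPHA_SW / _EMIS_LW) * (0.5 * sw_diffuse + 0.5 * sw_reflected + fp * direct_normal)
    )
    bad = radicand < 0.0
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        log.warning("negative MRT radicand in %d cells; marked missing", n_bad)
    with np.errstate(invalid="ignore"):
        out = np.where(bad, np.nan, np.maximum(radicand, 0.0) ** 0.25 - 273.15)
    return out if out.ndim else float(out)


def utci_polynomial(inp: UtciInput):
    """Evaluate the 6th-order UTCI polynomial, °C.

    Inputs are used as given (no caps or clamps); vapor pressure is
    converted hPa → kPa here, the only place that conversion happens.
    """
    ta = np.asarray(inp.t_air, dtype=float)
    va = np.asarray(inp.speed10, dtype=float)
    d = np.asarray(inp.t_mrt, dtype=float) - ta
    pa = np.asarray(inp.vapor_pressure, dtype=float) / 10.0  # hPa → kPa

    # precompute the power ladders once; cheaper and clearer than Horner
    # across four variables for a fixed 210-term table
    ta_p = [np.ones_like(ta)]
    va_p = [np.ones_like(va)]
    d_p = [np.ones_like(d)]
    pa_p = [np.ones_like(pa)]
    for p, base in ((ta_p, ta), (va_p, va), (d_p, d), (pa_p, pa)):
        for _ in range(6):
            p.append(p[-1] * base)

    offset = np.zeros(np.broadcast(ta, va, d, pa).shape)
    for c, i, j, k, l in UTCI_COEFFS:
        offset += c * ta_p[i] * va_p[j] * d_p[k] * pa_p[l]
    out = ta + offset
    return out if out.ndim else float(out)


def utci_from_fields(t_air, t_dew, speed10, t_mrt):
    """UTCI, °C, from air/dew-point temperature, 10 m wind, and MRT.

    Applies the operational guards: wind above 17 m/s → NaN; wind floored
    at 0.5 m/s; vapor pressure (Lawrence form, from dew point) raised to
    5% of saturation where relative humidity is below 5%.

    Returns
    -------
    utci : ndarray
        UTCI in °C (NaN where capped or any input missing).
    clamped : ndarray of bool
        True where the low-humidity clamp changed the vapor pressure.
    """
    t_air = np.asarray(t_air, dtype=float)
    t_dew = np.asarray(t_dew, dtype=float)
    speed10 = np.asarray(speed10, dtype=float)
    t_mrt = np.asarray(t_mrt, dtype=float)

    e_hpa = vapor_pressure_lawrence(t_dew) / 100.0
    es_hpa = vapor_pressure_lawrence(t_air) / 100.0
    clamped = e_hpa < _RH_CLAMP * es_hpa
    e_hpa = np.maximum(e_hpa, _RH_CLAMP * es_hpa)

    va = np.clip(speed10, _WIND_FLOOR, None)
    value = utci_polynomial(UtciInput(t_air=t_air, speed10=va,
                                      vapor_pressure=e_hpa, t_mrt=t_mrt))
    value = np.where(speed10 > WIND_CAP_MS, np.nan, value)
    n_capped = int(np.count_nonzero(np.asarray(speed10) > WIND_CAP_MS))
    n_clamped = int(np.count_nonzero(clamped & np.isfinite(t_air)))
    if n_capped or n_clamped:
        log.info("UTCI guards: %d wind-capped, %d humidity-clamped", n_capped, n_clamped)
    return value, clamped
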