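"""Scalar psychrometric building blocks shared by every heat metric.

Unit conventions at module boundaries:

* Lawrence-form operations (:func:`vapor_pressure_lawrence`,
  :func:`relative_humidity`) take temperatures in **°C** and return vapor
  pressure in **Pa** — these feed the simple indices and the reported
  relative humidity.
* Buck-form saturation pressure (:func:`esat_buck`) takes temperature in
  **K** and pressure in **hPa**, returning **hPa** — this is the form used
  inside the wet-bulb/globe energy-balance solvers.

All functions are pure, deterministic, and vectorize elementwise over numpy
arrays; NaN inputs propagate to NaN outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AirState",
    "WindVector",
    "vapor_pressure_lawrence",
    "relative_humidity",
    "buck_enhancement",
    "esat_buck",
    "wind_magnitude",
    "apply_wind_floor",
    "heat_of_vaporization_meyra",
    "heat_of_vaporization_linear",
    "WIND_FLOOR_MS",
]

#: Global minimum wind speed applied to every wind-consuming metric, m/s.
WIND_FLOOR_MS = 0.5

# Critical temperature of water, K, and the corresponding-states anchor for
# the latent-heat correlation (see heat_of_vaporization_meyra).
_T_CRIT_WATER = 647.096
_LATENT_ANCHOR_T = 313.15   # K
_LATENT_ANCHOR_L = 2.4073e6  # J/kg at 40 °C


@dataclass
class AirState:
    """Thermodynamic state of moist air near the surface.

    Attributes
    ----------
    t_air : array_like
        Dry-bulb (ambient) temperature, °C.
    t_dew : array_like
        Dew-point temperature, °C.  Physically ``t_dew <= t_air``.
    p_air : array_like
        Surface barometric pressure, hPa.
    """

    t_air: np.ndarray
    t_dew: np.ndarray
    p_air: np.ndarray


@dataclass
class WindVector:
    """10 m wind components, m/s (u zonal, v meridional)."""

    u: np.ndarray
    v: np.ndarray


def vapor_pressure_lawrence(t_dew):
    """Vapor pressure from dew point via the Lawrence (2005) formula.

    Parameters
    ----------
    t_dew : array_like
        Dew-point temperature, °C.

    Returns
    -------
    ndarray or float
        Vapor pressure, Pa: ``610.94 * exp(17.625*Td / (243.04 + Td))``.
    """
    t_dew = np.asarray(t_dew, dtype=float)
    out = 610.94 * np.exp(17.625 * t_dew / (243.04 + t_dew))
    return out if out.ndim else float(out)


def relative_humidity(t_air, t_dew):
    """Relative humidity, percent, as 100·e(Td)/e_s(Ta) (Lawrence form).

    Returns exactly 100 when ``t_dew == t_air``.  The raw ratio is returned
    without clipping; downstream consumers handle values above 100.
    """
    t_air = np.asarray(t_air, dtype=float)
    t_dew = np.asarray(t_dew, dtype=float)
    out = 100.0 * np.exp(
        17.625 * t_dew / (243.04 + t_dew) - 17.625 * t_air / (243.04 + t_air)
    )
    return out if out.ndim else float(out)


def buck_enhancement(p_air, variant="modified"):
    """Moist-air enhancement factor for saturation vapor pressure.

    ``modified`` uses the pressure-dependent Buck (1981, Eq. 8) factor
    ``1.0007 + 3.46e-6 * P`` (P in hPa); ``original`` uses the constant
    1.004 the unmodified energy-balance algorithm assumed (valid above
    ~800 hPa only).
    """
    p_air = np.asarray(p_air, dtype=float)
    if variant == "modified":
        out = 1.0007 + 3.46e-6 * p_air
    elif variant == "original":
        out = np.full_like(p_air, 1.004)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return out if out.ndim else float(out)


def esat_buck(t_air, p_air, variant="modified"):
    """Saturation vapor pressure over water, hPa (Buck 1981 form).

    Parameters
    ----------
    t_air : array_like
        Air temperature, **K**.
    p_air : array_like
        Barometric pressure, hPa.
    variant : {"modified", "original"}
        Selects the enhancement factor (see :func:`buck_enhancement`).

    Returns
    -------
    ndarray or float
        ``6.1121 * exp(17.502*(T-273.15)/(T-32.18)) * f(P)`` in hPa.
    """
    t_air = np.asarray(t_air, dtype=float)
    if np.any(t_air <= 32.18):
        raise ValueError("temperature at or below the 32.18 K pole is unphysical")
    out = 6.1121 * np.exp(17.502 * (t_air - 273.15) / (t_air - 32.18))
    out = out * buck_enhancement(p_air, variant)
    return out if out.ndim else float(out)


def wind_magnitude(u, v=None):
    """Wind speed magnitude sqrt(u² + v²) from components or a WindVector."""
    if isinstance(u, WindVector):
        u, v = u.u, u.v
    out = np.hypot(np.asarray(u, dtype=float), np.asarray(v, dtype=float))
    return out if out.ndim else float(out)


def apply_wind_floor(speed, floor=WIND_FLOOR_MS):
    """Floor a wind speed at ``floor`` m/s (default 0.5).

    Applied as a pre-processing step to the 10 m speed consumed by *all*
    wind-using metrics; very low reanalysis winds otherwise produce
    unreasonably high wet-bulb globe temperatures.
    """
    out = np.maximum(np.asarray(speed, dtype=float), floor)
    return out if out.ndim else float(out)


def heat_of_vaporization_meyra(t):
    """Latent heat of vaporization of water, J/kg (corresponding-states form).

    Generalized corresponding-states scaling with water's critical
    temperature (647.096 K) and the Watson exponent 0.38, anchored at
    313.15 K / 2.4073 MJ/kg:

    ``L(T) = L_ref * ((1 - T/Tc) / (1 - T_ref/Tc))**0.38``

    Agrees with steam-table values within 1% over the working range
    250–350 K and decreases monotonically with temperature.

    Parameters
    ----------
    t : array_like
        Temperature, K.
    """
    t = np.asarray(t, dtype=float)
    tr = 1.0 - t / _T_CRIT_WATER
    tr_ref = 1.0 - _LATENT_ANCHOR_T / _T_CRIT_WATER
    out = _LATENT_ANCHOR_L * (tr / tr_ref) ** 0.38
    return out if out.ndim else float(out)


def heat_of_vaporization_linear(t):
    """Latent heat, J/kg, linear-in-T form used by the original algorithm.

    ``L(T) = 2.4073e6 - 71100*(T - 313.15)/30`` — exact at 40 °C and within
    ~0.2% of steam tables from 0–40 °C.  Kept for the "original" variant of
    the wet-bulb solver.
    """
    t = np.asarray(t, dtype=float)
    out = (t - 313.15) / 30.0 * (-71100.0) + 2.4073e6
    return out if out.ndim else float(out)
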