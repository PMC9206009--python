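"""Closed-form heat metrics: heat index, humidex, net effective temperature.

All take °C inputs and return °C (or °C-equivalent index values).  The heat
index follows the U.S. National Weather Service operational scheme
(Rothfusz regression with the low- and high-humidity adjustment terms,
falling back to the Steadman average below the 80 °F threshold), evaluated
internally in Fahrenheit.  Humidex uses the hPa-scaled Lawrence vapor
pressure with the 6.1094 constant as printed in the source formulation
(differing in the third decimal from the Pa-form 610.94/100 = 6.1094 —
identical here, but kept as an explicit constant).  NET is a direct
evaluation of the printed closed form in temperature, relative humidity and
wind speed.
"""

from __future__ import annotations

import logging

import numpy as np

from .psychro import relative_humidity

__all__ = ["humidex", "net_effective_temperature", "heat_index_nws"]

log = logging.getLogger(__name__)


def humidex(t_air, t_dew):
    """Humidex, °C-equivalent: ``Ta + (5/9)·(e − 10)`` with e in hPa."""
    t_air = np.asarray(t_air, dtype=float)
    t_dew = np.asarray(t_dew, dtype=float)
    e = 6.1094 * np.exp(17.625 * t_dew / (243.04 + t_dew))
    out = t_air + (5.0 / 9.0) * (e - 10.0)
    return out if out.ndim else float(out)


def net_effective_temperature(t_air, rh, speed):
    """Net effective temperature, °C.

    ``37 − (37−Ta)/(0.68 − 0.0014·RH + 1/(1.76 + 1.4·w^0.75))
    − 0.29·Ta·(1 − RH/100)`` with RH in percent and w the (floored) wind
    speed in m/s.  The denominator cannot reach zero for RH <= 100; should
    pathological inputs drive it non-positive the value is marked missing.
    """
    t_air = np.asarray(t_air, dtype=float)
    rh = np.asarray(rh, dtype=float)
    speed = np.asarray(speed, dtype=float)
    denom = 0.68 - 0.0014 * rh + 1.0 / (1.76 + 1.4 * speed**0.75)
    bad = denom <= 0.0
    if np.any(bad):
        log.warning("NET denominator non-positive in %d cells; marked missing",
                    int(np.count_nonzero(bad)))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 37.0 - (37.0 - t_air) / denom - 0.29 * t_air * (1.0 - rh / 100.0)
    out = np.where(bad, np.nan, out)
    return out if out.ndim else float(out)


def heat_index_nws(t_air, t_dew):
    """Heat index, °C, per the National Weather Service algorithm.

    Relative humidity is derived from the dew point (Lawrence form).  The
    Steadman simple formula ``0.5·(T + 61 + (T−68)·1.2 + RH·0.094)`` (°F)
    applies when its average with the temperature is below 80 °F; otherwise
    the Rothfusz regression with the low-RH (RH < 13%, 80–112 °F) and
    high-RH (RH > 85%, 80–87 °F) adjustments.
    """
    t_air = np.asarray(t_air, dtype=float)
    t_dew = np.asarray(t_dew, dtype=float)
    rh = relative_humidity(t_air, t_dew)
    tf = t_air * 9.0 / 5.0 + 32.0

    simple = 0.5 * (tf + 61.0 + (tf - 68.0) * 1.2 + rh * 0.094)
    hi = np.where((simple + tf) / 2.0 < 80.0, simple, _rothfusz(tf, rh))
    out = (hi - 32.0) * 5.0 / 9.0
    return out if out.ndim else float(out)


def _rothfusz(tf, rh):
    hi = (
        -42.379
        + 2.04901523 * tf
        + 10.14333127 * rh
        - 0.22475541 * tf * rh
        - 6.83783e-3 * tf**2
        - 5.481717e-2 * rh**2
        + 1.22874e-3 * tf**2 * rh
        + 8.5282e-4 * tf * rh**2
        - 1.99e-6 * tf**2 * rh**2
    )
    low = (rh < 13.0) & (tf >= 80.0) & (tf <= 112.0)
    with np.errstate(invalid="ignore"):
        adj_low = (13.0 - rh) / 4.0 * np.sqrt(np.clip(17.0 - np.abs(tf - 95.0), 0.0, None) / 17.0)
    high = (rh > 85.0) & (tf >= 80.0) & (tf <= 87.0)
    adj_high = (rh - 85.0) / 10.0 * (87.0 - tf) / 5.0
    return hi - np.where(low, adj_low, 0.0) + np.where(high, adj_high, 0.0)
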