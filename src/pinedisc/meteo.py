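"""Vapor-pressure relations and the daytime averaging window.

Saturation vapor pressure follows the Tetens form
``es = 610.7 * 10**(7.5*T/(237.3+T)) / 1000`` (kPa, T in °C), VPD is
``es*(100-RH)/100``.  Daytime is the period from two hours after sunrise to
two hours before sunset; sunrise/sunset are supplied (hours of day), not
computed from solar geometry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def saturation_vapor_pressure(t_air):
    """Saturation vapor pressure e_s in kPa at air temperature ``t_air`` (°C)."""
    t = np.asarray(t_air, dtype=float)
    if np.any(t <= -237.3):
        raise ValueError("temperature out of range of the Tetens formula")
    es = 610.7 * 10.0 ** (7.5 * t / (237.3 + t)) / 1000.0
    return es if es.ndim else float(es)


def actual_vapor_pressure(t_air, rh):
    """Actual vapor pressure e_a = e_s * RH/100 in kPa."""
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("RH must be within [0, 100] %")
    ea = saturation_vapor_pressure(t_air) * rh / 100.0
    return ea if np.ndim(ea) else float(ea)


def vapor_pressure_deficit(t_air, rh):
    """VPD = e_s - e_a = e_s * (100 - RH)/100 in kPa."""
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("RH must be within [0, 100] %")
    vpd = saturation_vapor_pressure(t_air) * (100.0 - rh) / 100.0
    return vpd if np.ndim(vpd) else float(vpd)


def daytime_window(sunrise_hour: float, sunset_hour: float) -> tuple[float, float]:
    """Averaging window [sunrise + 2 h, sunset - 2 h] in hours of day.

    Raises if the day is 4 h or shorter (empty window).
    """
    if sunset_hour - sunrise_hour <= 4.0:
        raise ValueError("day length <= 4 h leaves an empty daytime window")
    return sunrise_hour + 2.0, sunset_hour - 2.0


def in_daytime_window(timestamps: pd.DatetimeIndex | pd.Series,
                      sunrise_hour: float, sunset_hour: float) -> np.ndarray:
    """Boolean mask: timestamp falls inside the daytime window."""
    lo, hi = daytime_window(sunrise_hour, sunset_hour)
    ts = pd.DatetimeIndex(timestamps)
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    return (hour >= lo) & (hour <= hi)


def daytime_mean(series: pd.Series, daytime_mask) -> pd.Series:
    """Per-day arithmetic mean of ``series`` over daytime records.

    ``series`` must be indexed by timestamps; ``daytime_mask`` is a boolean
    array aligned with it.
    """
    mask = np.asarray(daytime_mask, dtype=bool)
    sel = series[mask]
    if sel.empty:
        raise ValueError("no records inside the daytime window")
    return sel.groupby(pd.DatetimeIndex(sel.index).normalize()).mean()
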