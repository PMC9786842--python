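"""Steady-state photosynthetic 13C discrimination model.

The model expresses discrimination Δ (‰) against the intercellular CO2
drawdown, with corrections for mesophyll transfer, photorespiration and
day respiration::

    Δ = a + (b - a)·ci/ca - (b - a_m)·A/(g_m·ca) - f·Γ*/ca
        - R_d/(A + R_d) · e · (ci - Γ*)/ca

Γ* and R_d carry Arrhenius-type temperature responses referenced to 25 °C.
δ13C of new assimilates follows from Δ and δ13C of source air as
``δ_A = 1000·(δ_air - Δ)/(Δ + 1000)``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .params import R_GAS, T0_KELVIN, DiscriminationParams, RespirationParams

log = logging.getLogger(__name__)

#: Γ* at the 25 °C reference, µmol mol-1.
GAMMA_STAR_25 = 42.75
#: Activation energy of the Γ* response, J mol-1.
GAMMA_STAR_HA = 37_830.0


def _arrhenius(tl_c, h_a: float):
    tl = np.asarray(tl_c, dtype=float)
    return np.exp(h_a * (tl - 25.0) / (298.0 * R_GAS * (tl + T0_KELVIN)))


def gamma_star(tl_c, r_gas: float = R_GAS):
    """CO2 compensation point without dark respiration, µmol mol-1.

    Equals 42.75 µmol mol-1 at 25 °C and increases with leaf temperature.
    """
    tl = np.asarray(tl_c, dtype=float)
    out = GAMMA_STAR_25 * np.exp(
        GAMMA_STAR_HA * (tl - 25.0) / (298.0 * r_gas * (tl + T0_KELVIN)))
    return out if out.ndim else float(out)


def mitochondrial_respiration(tl_c, resp: RespirationParams):
    """Mitochondrial respiration R_d(T), µmol m-2 s-1 (all-sided area)."""
    out = resp.r_d0 * _arrhenius(tl_c, resp.h_alpha)
    return out if np.ndim(out) else float(out)


def fit_respiration(tl_c, efflux, min_records: int = 5,
                    min_span_c: float = 5.0) -> tuple[RespirationParams, float]:
    """Fit (R_d0, H_alpha) to night-time chamber efflux.

    Parameters
    ----------
    tl_c, efflux : array-like
        Night leaf (chamber air) temperatures, °C, and the matching CO2
        efflux magnitudes, µmol m-2 s-1 (positive = respiration).
    min_records, min_span_c :
        Identifiability guards: at least ``min_records`` records spanning
        at least ``min_span_c`` °C are required (a constant-temperature
        sample leaves H_alpha unidentifiable).

    Returns
    -------
    (RespirationParams, rmse)
    """
    tl = np.asarray(tl_c, dtype=float)
    ef = np.asarray(efflux, dtype=float)
    ok = np.isfinite(tl) & np.isfinite(ef)
    tl, ef = tl[ok], ef[ok]
    if tl.size < min_records:
        raise ValueError(f"need at least {min_records} night records, got {tl.size}")
    if np.ptp(tl) < min_span_c:
        raise ValueError(
            f"night temperatures span {np.ptp(tl):.2f} °C < {min_span_c} °C; "
            "H_alpha is not identifiable")

    def model(t, r_d0, h_alpha):
        return r_d0 * _arrhenius(t, h_alpha)

    p0 = (float(np.mean(ef)), 5e4)
    try:
        popt, _ = curve_fit(model, tl, ef, p0=p0, maxfev=10_000)
    except RuntimeError as err:
        raise RuntimeError(f"respiration fit did not converge: {err}") from err
    r_d0, h_alpha = popt
    if r_d0 < 0:
        raise ValueError(f"respiration fit returned negative R_d0 = {r_d0:.4g}")
    rmse = float(np.sqrt(np.mean((model(tl, *popt) - ef) ** 2)))
    return RespirationParams(r_d0=float(r_d0), h_alpha=float(h_alpha)), rmse


def model_discrimination(a_flux, ca, ci, tl_c,
                         params: DiscriminationParams = DiscriminationParams(),
                         resp: RespirationParams = RespirationParams()):
    """Photosynthetic discrimination Δ in ‰.

    ``a_flux`` is net assimilation A (µmol m-2 s-1), ``ca``/``ci`` the
    ambient and intercellular CO2 mole fractions (ppm), ``tl_c`` leaf
    temperature (°C).  With ``params.g_m`` infinite the mesophyll term is
    zero; with ``resp.light_inhibited`` the respiratory term is zero.
    """
    a_flux = np.asarray(a_flux, dtype=float)
    ca = np.asarray(ca, dtype=float)
    ci = np.asarray(ci, dtype=float)
    g_star = gamma_star(tl_c)
    r_d = 0.0 if resp.light_inhibited else mitochondrial_respiration(tl_c, resp)
    denom = a_flux + r_d
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("A + R_d must be positive for the discrimination model")
    gm_term = 0.0 if params.infinite_gm else (params.b - params.a_m) * a_flux / (params.g_m * ca)
    delta = (params.a
             + (params.b - params.a) * ci / ca
             - gm_term
             - params.f * g_star / ca
             - (r_d / denom) * params.e * (ci - g_star) / ca)
    return delta if np.ndim(delta) else float(delta)


def delta_from_discrimination(delta13c_air, delta_cap):
    """δ13C of assimilates from source-air δ13C and discrimination Δ (all ‰)."""
    delta_cap = np.asarray(delta_cap, dtype=float)
    if np.any(delta_cap <= -1000.0):
        raise ValueError("Δ must exceed -1000 ‰")
    out = 1000.0 * (np.asarray(delta13c_air, dtype=float) - delta_cap) / (delta_cap + 1000.0)
    return out if out.ndim else float(out)


def discrimination_from_delta(delta13c_air, delta13c_a):
    """Inverse conversion: Δ from δ13C of air and of assimilates (all ‰)."""
    delta13c_a = np.asarray(delta13c_a, dtype=float)
    if np.any(delta13c_a <= -1000.0):
        raise ValueError("δ13C_A must exceed -1000 ‰")
    out = 1000.0 * (np.asarray(delta13c_air, dtype=float) - delta13c_a) / (1000.0 + delta13c_a)
    return out if out.ndim else float(out)


def model_delta_series(gasex: pd.DataFrame, env: pd.DataFrame,
                       params: DiscriminationParams = DiscriminationParams(),
                       resp: RespirationParams = RespirationParams(),
                       sunrise_hour: float = 4.0,
                       sunset_hour: float = 22.0) -> pd.Series:
    """Daily flux-weighted daytime mean modeled δ13C of assimilates.

    ``gasex`` needs columns ``timestamp, a, e`` (net CO2 flux µmol m-2 s-1
    and transpiration mmol m-2 s-1, e.g. QC-passing chamber fluxes);
    ``env`` supplies ``timestamp, t_air, rh, p_amb, ca, delta13c_air``.
    Records where the model is invalid (A + R_d ≤ 0, VPD = 0, ci ≤ Γ*)
    are dropped with a log message.  Leaf temperature is taken equal to
    the chamber air temperature.
    """
    from .iwue import iwue_gas
    from .meteo import (actual_vapor_pressure, in_daytime_window,
                        saturation_vapor_pressure)

    df = pd.merge(gasex, env, on="timestamp", how="inner", suffixes=("", "_env"))
    if df.empty:
        raise ValueError("no overlapping timestamps between gasex and env")
    es = saturation_vapor_pressure(df["t_air"].to_numpy())
    ea = actual_vapor_pressure(df["t_air"].to_numpy(), df["rh"].to_numpy())
    valid = (df["a"].to_numpy() > 0) & (df["e"].to_numpy() > 0) & (es > ea)
    n_bad = int((~valid).sum())
    if n_bad:
        log.info("model_delta_series: dropping %d records with non-positive "
                 "fluxes or zero VPD", n_bad)
    df = df[valid].copy()
    es, ea = es[valid], ea[valid]
    _, iwue = iwue_gas(df["a"].to_numpy(), df["e"].to_numpy(), es, ea,
                       df["p_amb"].to_numpy())
    ci = df["ca"].to_numpy() - 1.6 * iwue
    g_star = gamma_star(df["t_air"].to_numpy())
    ok = ci > g_star
    if not np.all(ok):
        log.info("model_delta_series: dropping %d records with ci <= Γ*",
                 int((~ok).sum()))
        df, ci = df[ok].copy(), ci[ok]
    if df.empty:
        raise ValueError("no valid daytime records for the discrimination model")
    delta_cap = model_discrimination(df["a"].to_numpy(), df["ca"].to_numpy(),
                                     ci, df["t_air"].to_numpy(), params, resp)
    delta_a = delta_from_discrimination(df["delta13c_air"].to_numpy(), delta_cap)
    mask = in_daytime_window(df["timestamp"], sunrise_hour, sunset_hour)
    from .chamber import flux_weighted_daytime_mean
    return flux_weighted_daytime_mean(
        pd.Series(delta_a, index=pd.DatetimeIndex(df["timestamp"])),
        pd.Series(df["a"].to_numpy(), index=pd.DatetimeIndex(df["timestamp"])),
        mask)
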