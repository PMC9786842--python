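"""Closure-trace flux estimation, δ13C_A_Picarro, QC and daytime averaging.

A non-airtight shoot chamber of volume V is closed for 65 s while sample
air is drawn to the analysers at flow q and replaced by ambient leak-in.
Each gas species then follows the first-order mass balance

    dC/dt = (q/V)·(C_amb - C) - F·S/n_air,

whose solution ``C(t) = C_eq + (C0 - C_eq)·exp(-k·t)`` (k = q/V) is fitted
by nonlinear least squares.  The flux per all-sided needle area S follows
from the fitted equilibrium deficit, ``F = n_flow·(C_amb - C_eq)/S`` with
``n_flow = q·P/(R·T)`` the molar sample flow.  Uptake is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .params import R_GAS, R_VPDB, T0_KELVIN, ChamberSpec, ratio_to_delta

log = logging.getLogger(__name__)

#: Nonlinear-fit windows in seconds since closure: the Picarro isotopologue
#: channels use 5-50 s, the slower LI-840 CO2/H2O channels 5-35 s.
FIT_WINDOWS = {"c12": (5.0, 50.0), "c13": (5.0, 50.0),
               "co2": (5.0, 35.0), "h2o": (5.0, 35.0)}

#: QC thresholds: δ13C discarded when the CO2 flux is lower than
#: 0.5 µmol m-2 s-1; H2O flux discarded when chamber RH exceeds 75 %.
QC_MIN_CO2_FLUX = 0.5
QC_MAX_RH = 75.0


@dataclass
class ClosureTrace:
    """One chamber-closure event.

    ``t_fast/c12/c13`` are the 0.5 s isotopologue concentrations (ppm),
    ``t_slow/co2/h2o`` the 5 s bulk CO2 and water vapor (ppm).  Ambient
    CO2 and δ13C_air are the pre-closure values.
    """

    closure_id: str
    timestamp: pd.Timestamp
    t_fast: np.ndarray
    c12: np.ndarray
    c13: np.ndarray
    t_slow: np.ndarray
    co2: np.ndarray
    h2o: np.ndarray
    chamber: ChamberSpec
    ca_ambient: float
    delta13c_air: float
    t_chamber_c: float
    rh_chamber: float
    p_amb_kpa: float

    def __post_init__(self) -> None:
        for t in (self.t_fast, self.t_slow):
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.chamber.closure_seconds):
                raise ValueError("closure timestamps must be strictly increasing within [0, 65] s")


@dataclass
class FluxFit:
    """Result of fitting one species of one closure."""

    flux: float                  # µmol m-2 s-1 (uptake positive)
    c_eq: float
    c0: float
    k: float
    rmse: float
    converged: bool
    flat: bool
    pcov: np.ndarray | None = None


@dataclass
class FluxRecord:
    """Fitted fluxes and δ13C_A_Picarro for one closure."""

    closure_id: str
    timestamp: pd.Timestamp
    f12: float
    f13: float
    f_co2: float
    f_h2o: float                 # transpiration, mmol m-2 s-1 (release positive)
    delta13c_a_picarro: float
    t_chamber_c: float
    rh_chamber: float
    qc_co2_pass: bool
    qc_h2o_pass: bool
    rmse_c12: float
    rmse_c13: float
    rmse_co2: float
    rmse_h2o: float


def molar_flow(sample_flow_dm3_min: float, p_amb_kpa: float, t_c: float) -> float:
    """Molar sample flow q·P/(R·T) in mol s-1 (ideal gas)."""
    q_m3_s = sample_flow_dm3_min / 1000.0 / 60.0
    return q_m3_s * p_amb_kpa * 1000.0 / (R_GAS * (t_c + T0_KELVIN))


def _exp_model(t, c0, c_eq, k):
    return c_eq + (c0 - c_eq) * np.exp(-k * t)


def fit_closure_flux(trace: ClosureTrace, species: str,
                     c_amb: float | None = None,
                     fit_rate_constant: bool = False) -> FluxFit:
    """Fit the exponential dilution model to one species of a closure.

    ``species`` is one of ``c12, c13, co2, h2o``; the fit window is
    5-50 s for the fast channels and 5-35 s for the slow ones.  For H2O
    the returned flux keeps the uptake-positive convention (transpiration
    therefore appears negative; :func:`process_trace` flips it).

    The dilution rate constant k = q/V is known from the chamber hardware
    and is held fixed by default: a 65 s closure spans less than one time
    constant, so freeing k lets it trade off against C_eq on noisy traces.
    ``fit_rate_constant=True`` frees it anyway.
    """
    if species not in FIT_WINDOWS:
        raise ValueError(f"unknown species {species!r}")
    if species in ("c12", "c13"):
        t = np.asarray(trace.t_fast, dtype=float)
        c = np.asarray(getattr(trace, species), dtype=float)
    else:
        t = np.asarray(trace.t_slow, dtype=float)
        c = np.asarray(getattr(trace, species), dtype=float)
    lo, hi = FIT_WINDOWS[species]
    sel = (t >= lo) & (t <= hi)
    t, c = t[sel], c[sel]
    if t.size < 6:
        raise ValueError(f"fewer than 6 points in the {species} fit window")

    chamber = trace.chamber
    n_flow = molar_flow(chamber.sample_flow_dm3_min, trace.p_amb_kpa, trace.t_chamber_c)
    if c_amb is None:
        c_amb = _ambient_concentration(trace, species)

    k0 = chamber.sample_flow_dm3_min / 60.0 / chamber.volume_dm3
    if np.ptp(c) < 1e-12:
        # perfectly flat trace: zero equilibrium deficit, nothing to fit
        flux = n_flow * (c_amb - c[0]) / chamber.needle_area_m2
        log.warning("closure %s %s: flat trace, returning equilibrium flux %.3g",
                    trace.closure_id, species, flux)
        return FluxFit(flux=float(flux), c_eq=float(c[0]), c0=float(c[0]), k=k0,
                       rmse=0.0, converged=True, flat=True)

    c_eq0 = c[-1] + (c[-1] - c[0]) * np.exp(-k0 * t[-1]) / max(1e-9, 1 - np.exp(-k0 * t[-1]))
    try:
        if fit_rate_constant:
            popt, pcov = curve_fit(_exp_model, t, c, p0=(c[0], c_eq0, k0),
                                   bounds=([-np.inf, -np.inf, 1e-6],
                                           [np.inf, np.inf, 10.0]),
                                   maxfev=10_000)
            c0_fit, c_eq, k = popt
        else:
            popt, pcov = curve_fit(lambda tt, c0, ceq: _exp_model(tt, c0, ceq, k0),
                                   t, c, p0=(c[0], c_eq0), maxfev=10_000)
            c0_fit, c_eq = popt
            k = k0
    except RuntimeError as err:
        raise RuntimeError(
            f"closure {trace.closure_id} {species}: fit did not converge") from err
    rmse = float(np.sqrt(np.mean((_exp_model(t, c0_fit, c_eq, k) - c) ** 2)))
    flux = n_flow * (c_amb - c_eq) / chamber.needle_area_m2
    return FluxFit(flux=float(flux), c_eq=float(c_eq), c0=float(c0_fit),
                   k=float(k), rmse=rmse, converged=True, flat=False, pcov=pcov)


def _ambient_concentration(trace: ClosureTrace, species: str) -> float:
    """Pre-closure ambient mole fraction of a species, ppm."""
    from .meteo import actual_vapor_pressure
    if species == "co2":
        return trace.ca_ambient
    if species == "h2o":
        ea = actual_vapor_pressure(trace.t_chamber_c, trace.rh_chamber)
        return ea / trace.p_amb_kpa * 1e6
    r_amb = R_VPDB * (1.0 + trace.delta13c_air / 1000.0)
    c12_amb = trace.ca_ambient / (1.0 + r_amb)
    return c12_amb if species == "c12" else trace.ca_ambient - c12_amb


def delta13c_from_fluxes(f13, f12):
    """δ13C (‰ vs V-PDB) of the assimilated CO2 from the isotopologue fluxes."""
    f12 = np.asarray(f12, dtype=float)
    if np.any(f12 <= 0):
        raise ValueError("12CO2 flux must be positive to form a flux ratio")
    out = ratio_to_delta(np.asarray(f13, dtype=float) / f12)
    return out if np.ndim(out) else float(out)


def process_trace(trace: ClosureTrace) -> FluxRecord:
    """Fit all four species of one closure and assemble a FluxRecord.

    δ13C_A_Picarro is NaN when the 12CO2 flux is non-positive (no
    meaningful uptake ratio, e.g. night efflux).
    """
    fit12 = fit_closure_flux(trace, "c12")
    fit13 = fit_closure_flux(trace, "c13")
    fitco2 = fit_closure_flux(trace, "co2")
    fith2o = fit_closure_flux(trace, "h2o")
    if fit12.flux > 0:
        delta = delta13c_from_fluxes(fit13.flux, fit12.flux)
    else:
        delta = float("nan")
    f_h2o = -fith2o.flux / 1000.0  # release positive, mmol m-2 s-1
    return FluxRecord(
        closure_id=trace.closure_id, timestamp=trace.timestamp,
        f12=fit12.flux, f13=fit13.flux, f_co2=fitco2.flux, f_h2o=f_h2o,
        delta13c_a_picarro=delta,
        t_chamber_c=trace.t_chamber_c, rh_chamber=trace.rh_chamber,
        qc_co2_pass=not (fitco2.flux < QC_MIN_CO2_FLUX),
        qc_h2o_pass=not (trace.rh_chamber > QC_MAX_RH),
        rmse_c12=fit12.rmse, rmse_c13=fit13.rmse,
        rmse_co2=fitco2.rmse, rmse_h2o=fith2o.rmse)


def fluxes_to_frame(records: list[FluxRecord]) -> pd.DataFrame:
    """Tabulate FluxRecords, one row per closure."""
    return pd.DataFrame([vars(r) for r in records])


def qc_filter(fluxes: pd.DataFrame,
              min_co2_flux: float = QC_MIN_CO2_FLUX,
              max_rh: float = QC_MAX_RH) -> pd.DataFrame:
    """Apply the two QC rules, nulling (not altering) failing entries.

    δ13C_A_Picarro is set to NaN where the CO2 flux is strictly below
    ``min_co2_flux``; the H2O flux is set to NaN where chamber RH strictly
    exceeds ``max_rh``.  Removal counts are logged.
    """
    out = fluxes.copy()
    low = out["f_co2"] < min_co2_flux
    wet = out["rh_chamber"] > max_rh
    out.loc[low, "delta13c_a_picarro"] = np.nan
    out.loc[wet, "f_h2o"] = np.nan
    out["qc_co2_pass"] = ~low
    out["qc_h2o_pass"] = ~wet
    log.info("qc_filter: removed %d/%d δ13C records (CO2 flux < %.2g) and "
             "%d H2O fluxes (RH > %.3g %%)",
             int(low.sum()), len(out), min_co2_flux, int(wet.sum()), max_rh)
    return out


def flux_weighted_daytime_mean(values: pd.Series, weights: pd.Series,
                               daytime_mask) -> pd.Series:
    """Per-day flux-weighted mean Σ(wᵢ·xᵢ)/Σwᵢ over daytime records.

    ``values`` and ``weights`` share a timestamp index; NaN values are
    excluded together with their weights.  Days whose daytime weights are
    all zero (or all values missing) raise.
    """
    mask = np.asarray(daytime_mask, dtype=bool)
    w = np.asarray(weights, dtype=float)
    if np.any(w[mask & np.isfinite(w)] < 0):
        raise ValueError("weights must be non-negative")
    df = pd.DataFrame({"x": values.to_numpy(), "w": w},
                      index=pd.DatetimeIndex(values.index))
    df = df[mask].dropna()
    if df.empty:
        raise ValueError("no usable daytime records")

    def _wmean(g: pd.DataFrame) -> float:
        sw = g["w"].sum()
        if sw <= 0:
            raise ValueError(
                f"all-zero weights in daytime window on {g.index[0].date()}")
        return float((g["x"] * g["w"]).sum() / sw)

    return df.groupby(df.index.normalize()).apply(_wmean)
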