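"""Synthetic season generator with known ground truth.

Emulates the four data streams of a boreal Scots pine chamber campaign:
micrometeorological drivers, shoot gas exchange (with the true
discrimination attached), chamber-closure concentration traces, and dated
δ13C series of leaf carbon pools (sucrose, pinitol, WSC, starch, TOM) for
two needle generations.  Every downstream stage of the pipeline can
therefore be tested against exact truth.

The pool mixing structure follows the field behaviour of the system:
sucrose integrates the assimilate signal over a few days with a geometric
previous-day weight; pinitol and starch are isotopically invariant; WSC is
a pinitol/sugar mixture (~40/60); TOM tracks assimilates only while the
needle is growing and freezes thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import meteo
from .carryover import integrate_carryover
from .chamber import ClosureTrace, molar_flow
from .discrimination import (delta_from_discrimination, gamma_star,
                             mitochondrial_respiration, model_discrimination)
from .params import (R_VPDB, ChamberSpec, DiscriminationParams,
                     RespirationParams, delta_to_ratio)


@dataclass(frozen=True)
class SeasonConfig:
    """Drivers of one synthetic growing season (boreal defaults)."""

    start_date: str = "2018-05-01"
    end_date: str = "2018-10-15"
    timestep_minutes: int = 10
    sunrise_hour: float = 4.0
    sunset_hour: float = 22.0
    par_max: float = 1400.0          # clear-sky midday PAR, µmol m-2 s-1
    t_mean_seasonal: float = 11.0    # °C
    t_amplitude: float = 8.0         # seasonal half-range, °C
    t_diel_amplitude: float = 4.0    # day-night half-range, °C
    t_noise_sd: float = 2.5          # day-to-day Gaussian wobble, °C
    rh_base: float = 70.0            # %
    rh_t_slope: float = -1.8         # % per °C anomaly (RH anti-correlates with T)
    rh_noise_sd: float = 8.0
    p_amb: float = 98.8              # kPa at 170 m a.s.l.
    ca_ambient: float = 405.0        # ppm
    delta13c_air: float = -8.5       # ‰
    rain_probability: float = 0.25   # per day, outside the dry period
    rain_mm_mean: float = 4.0
    soil_moisture_base: float = 0.30  # m3 m-3
    dry_period: tuple[str, str] | None = ("2018-08-16", "2018-09-10")
    soil_moisture_floor: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if pd.Timestamp(self.start_date) >= pd.Timestamp(self.end_date):
            raise ValueError("start_date must precede end_date")
        if self.timestep_minutes <= 0 or 1440 % self.timestep_minutes:
            raise ValueError("timestep must be positive and divide a day")
        if self.par_max <= 0:
            raise ValueError("PAR_max must be positive")
        if not (0 < self.rh_base <= 100):
            raise ValueError("RH_base must lie in (0, 100]")


@dataclass(frozen=True)
class PhysiologyConfig:
    """Light response and stomatal behaviour of the synthetic shoot.

    Assimilation is a saturating light response with a Gaussian
    temperature modifier.  Stomata follow the optimal-stomatal-control
    schedule ``iWUE = ca·√VPD / (1.6·(g1 + √VPD))`` (Medlyn form) with a
    drought add-on below a soil-moisture threshold, from which g_s, E and
    ci derive.  Values are per all-sided needle area.
    """

    a_max: float = 8.0               # light-saturated net A, µmol m-2 s-1
    quantum_yield: float = 0.03      # initial slope, µmol CO2 / µmol photons
    t_opt: float = 18.0              # °C
    t_sigma: float = 12.0            # °C
    g1_kpa_sqrt: float = 1.6         # Medlyn slope, kPa^0.5 (boreal pine)
    iwue_soil_slope: float = 250.0   # ppm per m3 m-3 of soil-water deficit
    iwue_soil_threshold: float = 0.20  # m3 m-3; stomata respond below this
    iwue_min: float = 55.0
    iwue_max: float = 170.0
    delta13c_respired: float = -26.0  # ‰, night efflux isotopic signature


@dataclass(frozen=True)
class PoolMixingSpec:
    """How one leaf carbon pool of one needle generation mixes assimilates."""

    pool_name: str                  # sucrose | pinitol | WSC | starch | TOM
    generation: str                 # 0N | 1N
    carryover_days: int = 4
    previous_day_weight: float = 0.8
    invariant_value: float | None = None   # ‰; pinitol/starch/frozen pools
    pinitol_share: float = 0.4             # WSC only
    pinitol_value: float = -31.0           # ‰, WSC mixing end-member
    growth_window: tuple[str, str] | None = None  # TOM only
    noise_sd: float = 0.0           # ‰
    offset_vs_assimilates: float = 0.0     # ‰

    def __post_init__(self) -> None:
        if self.carryover_days < 0:
            raise ValueError("carry-over days must be >= 0")
        if not (0 < self.previous_day_weight <= 1):
            raise ValueError("previous-day weight must lie in (0, 1]")
        if not (0 <= self.pinitol_share <= 1):
            raise ValueError("pinitol share must lie in [0, 1]")


def generate_environment(config: SeasonConfig) -> pd.DataFrame:
    """Simulate the micrometeorological record at the configured timestep.

    Diurnal PAR is a half-sine between sunrise and sunset scaled by a
    seasonal factor and a per-day cloudiness draw; temperature combines a
    seasonal sinusoid, a diel cycle and day-level Gaussian noise; RH is
    anti-correlated with the temperature anomaly.  Deterministic for a
    given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    ts = pd.date_range(config.start_date, config.end_date,
                       freq=f"{config.timestep_minutes}min", inclusive="left")
    hour = ts.hour + ts.minute / 60.0
    doy = ts.dayofyear.to_numpy().astype(float)
    days = pd.DatetimeIndex(ts.normalize()).unique()
    day_key = pd.Series(np.arange(len(days)), index=days)
    day_ix = day_key.loc[ts.normalize()].to_numpy()

    # per-day draws
    cloud = rng.uniform(0.45, 1.0, len(days))
    t_daily = rng.normal(0.0, config.t_noise_sd, len(days))
    rh_daily = rng.normal(0.0, config.rh_noise_sd, len(days))
    raining = rng.random(len(days)) < config.rain_probability
    rain_mm = np.where(raining, rng.exponential(config.rain_mm_mean, len(days)), 0.0)

    dry = np.zeros(len(days), dtype=bool)
    if config.dry_period is not None:
        d0, d1 = map(pd.Timestamp, config.dry_period)
        dry = (days >= d0) & (days <= d1)
        rain_mm[dry] = 0.0
    cloud[raining & ~dry] *= 0.5

    # seasonal envelopes (peak near day 200 = late July)
    seasonal_t = config.t_mean_seasonal + config.t_amplitude * np.cos(
        2 * np.pi * (doy - 200.0) / 365.0)
    seasonal_par = 0.55 + 0.45 * np.cos(2 * np.pi * (doy - 172.0) / 365.0)

    sr, ss = config.sunrise_hour, config.sunset_hour
    sun_up = (hour >= sr) & (hour <= ss)
    par = np.where(sun_up,
                   config.par_max * seasonal_par * cloud[day_ix]
                   * np.sin(np.pi * np.clip((hour - sr) / (ss - sr), 0, 1)),
                   0.0)
    par = np.clip(par, 0.0, None)
    par[par < 1e-9] = 0.0  # kill sin(pi) floating-point residue at sunset

    diel = -config.t_diel_amplitude * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    t_air = seasonal_t + diel + t_daily[day_ix]
    t_anom = t_air - seasonal_t.mean()
    rh = np.clip(config.rh_base + config.rh_t_slope * t_anom + rh_daily[day_ix],
                 25.0, 97.0)
    rh = np.where(raining[day_ix], np.minimum(rh + 15.0, 97.0), rh)

    es = meteo.saturation_vapor_pressure(t_air)
    ea = meteo.actual_vapor_pressure(t_air, rh)

    soil = np.full(len(days), config.soil_moisture_base)
    if dry.any():
        # linear drawdown to the floor, linear recovery afterwards
        ix = np.flatnonzero(dry)
        frac = np.linspace(0.0, 1.0, ix.size)
        soil[ix] = config.soil_moisture_base - frac * (
            config.soil_moisture_base - config.soil_moisture_floor)
        after = np.arange(ix[-1] + 1, len(days))
        if after.size:
            rec = np.minimum(1.0, (after - ix[-1]) / 10.0)
            soil[after] = config.soil_moisture_floor + rec * (
                config.soil_moisture_base - config.soil_moisture_floor)
    soil = soil + rain_mm * 0.002  # small wetting response

    env = pd.DataFrame({
        "timestamp": ts,
        "par": par,
        "t_air": t_air,
        "rh": rh,
        "es": es,
        "ea": ea,
        "vpd": es - ea,
        "p_amb": config.p_amb,
        "precipitation": rain_mm[day_ix] * config.timestep_minutes / 1440.0,
        "soil_moisture": soil[day_ix],
        "ca": config.ca_ambient,
        "delta13c_air": config.delta13c_air,
        "is_daytime": meteo.in_daytime_window(ts, sr, ss),
    })
    return env


def generate_gas_exchange(env: pd.DataFrame,
                          phys: PhysiologyConfig = PhysiologyConfig(),
                          params: DiscriminationParams = DiscriminationParams(),
                          resp: RespirationParams = RespirationParams(),
                          ) -> pd.DataFrame:
    """Forward-model shoot gas exchange and its true discrimination.

    Daytime (PAR > 0): A from the light response, iWUE from the VPD
    schedule, g_s = A/iWUE, E = g_s·VPD/P, ci = ca - 1.6·iWUE, Δ from the
    discrimination model and δ13C_A from Δ and δ13C_air — so the truth is
    self-consistent with the model by construction.  Night: A is the
    respiratory efflux -R_d(T).  Raises if the iWUE schedule would push
    ci below Γ* (outside model validity).
    """
    if env.empty:
        raise ValueError("empty environment table")
    par = env["par"].to_numpy()
    t_air = env["t_air"].to_numpy()
    vpd = env["vpd"].to_numpy()
    ca = env["ca"].to_numpy()

    day = par > 0
    a = np.where(day,
                 phys.a_max * (1.0 - np.exp(-phys.quantum_yield * par / phys.a_max))
                 * np.exp(-0.5 * ((t_air - phys.t_opt) / phys.t_sigma) ** 2),
                 -mitochondrial_respiration(t_air, resp))
    soil_deficit = np.clip(phys.iwue_soil_threshold - env["soil_moisture"].to_numpy(),
                           0.0, None)
    sqrt_vpd = np.sqrt(np.clip(vpd, 1e-6, None))
    iwue = np.clip(ca * sqrt_vpd / (1.6 * (phys.g1_kpa_sqrt + sqrt_vpd))
                   + phys.iwue_soil_slope * soil_deficit,
                   phys.iwue_min, phys.iwue_max)
    ci = np.where(day, ca - 1.6 * iwue, np.nan)
    g_star = gamma_star(t_air)
    if np.any(day & (ci <= g_star)):
        raise ValueError("configured iWUE schedule forces ci <= Γ* "
                         "(discrimination model invalid)")
    gs = np.where(day, a / iwue, 0.0)                   # mol m-2 s-1
    e = np.where(day, gs * 1000.0 * vpd / env["p_amb"].to_numpy(), 0.0)  # mmol

    delta_cap = np.full(len(env), np.nan)
    delta_a = np.full(len(env), np.nan)
    if day.any():
        delta_cap[day] = model_discrimination(a[day], ca[day], ci[day],
                                              t_air[day], params, resp)
        delta_a[day] = delta_from_discrimination(
            env["delta13c_air"].to_numpy()[day], delta_cap[day])

    return pd.DataFrame({
        "timestamp": env["timestamp"].to_numpy(),
        "a": a,
        "e": e,
        "gs": gs,
        "t_leaf": t_air,
        "ci": ci,
        "iwue_true": np.where(day, iwue, np.nan),
        "delta_cap_true": delta_cap,
        "delta13c_a_true": delta_a,
    })


def generate_closure_trace(truth_row: pd.Series, env_row: pd.Series,
                           chamber: ChamberSpec = ChamberSpec(),
                           noise_sd: float = 0.0,
                           rng: np.random.Generator | None = None,
                           closure_id: str | None = None,
                           delta13c_respired: float = -26.0) -> ClosureTrace:
    """Build one closure trace consistent with the first-order mass balance.

    The 13CO2 trace is constructed so the 13C/12C flux ratio encodes the
    record's true assimilate δ13C (or the respired signature at night).
    ``noise_sd`` (ppm) applies to the 12CO2 and bulk CO2 channels; the
    13CO2 channel is scaled by the isotopologue abundance ratio and the
    H2O channel by 100x (water is measured in thousands of ppm).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    a = float(truth_row["a"])
    e = float(truth_row["e"])
    ca = float(env_row["ca"])
    d_air = float(env_row["delta13c_air"])
    t_c = float(env_row["t_air"])
    rh = float(env_row["rh"])
    p = float(env_row["p_amb"])

    n_flow = molar_flow(chamber.sample_flow_dm3_min, p, t_c)
    k = chamber.sample_flow_dm3_min / 60.0 / chamber.volume_dm3
    s_area = chamber.needle_area_m2

    d_flux = float(truth_row["delta13c_a_true"]) if a > 0 else delta13c_respired
    r_flux = delta_to_ratio(d_flux)
    f12 = a / (1.0 + r_flux)
    f13 = a - f12
    r_amb = delta_to_ratio(d_air)
    c12_amb = ca / (1.0 + r_amb)
    c13_amb = ca - c12_amb
    h2o_amb = meteo.actual_vapor_pressure(t_c, rh) / p * 1e6

    t_fast = np.arange(0.0, chamber.closure_seconds + 1e-9, chamber.fast_dt_s)
    t_slow = np.arange(0.0, chamber.closure_seconds + 1e-9, chamber.slow_dt_s)

    def trace(t, c_amb, flux_uptake, sd):
        c_eq = c_amb - flux_uptake * s_area / n_flow
        c = c_eq + (c_amb - c_eq) * np.exp(-k * t)
        if sd > 0:
            c = c + rng.normal(0.0, sd, t.size)
        return c

    return ClosureTrace(
        closure_id=closure_id or pd.Timestamp(truth_row["timestamp"]).strftime("%Y%m%d_%H%M%S"),
        timestamp=pd.Timestamp(truth_row["timestamp"]),
        t_fast=t_fast,
        c12=trace(t_fast, c12_amb, f12, noise_sd),
        c13=trace(t_fast, c13_amb, f13, noise_sd * R_VPDB),
        t_slow=t_slow,
        co2=trace(t_slow, ca, a, noise_sd),
        h2o=trace(t_slow, h2o_amb, -e * 1000.0, noise_sd * 100.0),
        chamber=chamber,
        ca_ambient=ca, delta13c_air=d_air,
        t_chamber_c=t_c, rh_chamber=rh, p_amb_kpa=p)


def generate_closure_traces(gasex: pd.DataFrame, env: pd.DataFrame,
                            chamber: ChamberSpec = ChamberSpec(),
                            schedule_minutes: int = 30,
                            noise_sd: float = 0.0,
                            rng_seed: int = 0,
                            delta13c_respired: float = -26.0) -> list[ClosureTrace]:
    """Closure traces on a regular schedule across the season.

    One closure every ``schedule_minutes`` (day and night; night closures
    carry the respiratory efflux that the respiration fit consumes).
    """
    rng = np.random.default_rng(rng_seed)
    df = pd.merge(gasex, env, on="timestamp", how="inner")
    minutes = pd.DatetimeIndex(df["timestamp"])
    keep = ((minutes.hour * 60 + minutes.minute) % schedule_minutes) == 0
    traces = []
    for _, row in df[keep].iterrows():
        traces.append(generate_closure_trace(
            row, row, chamber=chamber, noise_sd=noise_sd, rng=rng,
            delta13c_respired=delta13c_respired))
    return traces


def daily_assimilate_signal(gasex: pd.DataFrame,
                            sunrise_hour: float = 4.0,
                            sunset_hour: float = 22.0) -> pd.Series:
    """Daily assimilation-weighted daytime mean of true assimilate δ13C."""
    from .chamber import flux_weighted_daytime_mean
    ts = pd.DatetimeIndex(gasex["timestamp"])
    mask = meteo.in_daytime_window(ts, sunrise_hour, sunset_hour) \
        & (gasex["a"].to_numpy() > 0)
    return flux_weighted_daytime_mean(
        pd.Series(gasex["delta13c_a_true"].to_numpy(), index=ts),
        pd.Series(gasex["a"].to_numpy(), index=ts), mask)


def generate_pool_series(daily_delta: pd.Series, spec: PoolMixingSpec,
                         sampling_dates, rng: np.random.Generator | None = None
                         ) -> pd.Series:
    """δ13C series of one carbon pool at the requested sampling dates.

    ``daily_delta`` is the daily assimilate δ13C signal and must cover the
    look-back window ``carryover_days`` before the first sampling date.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    dates = pd.DatetimeIndex(sampling_dates).normalize().sort_values()
    daily_idx = pd.DatetimeIndex(daily_delta.index).normalize()
    daily = pd.Series(daily_delta.to_numpy(dtype=float), index=daily_idx)

    n, lam = spec.carryover_days, spec.previous_day_weight
    need_from = dates.min() - pd.Timedelta(days=n)
    if spec.invariant_value is None and need_from < daily_idx.min():
        raise ValueError(
            f"daily assimilate signal must reach back to {need_from.date()} "
            f"to cover the {n}-day look-back window")

    name = spec.pool_name
    if name in ("pinitol", "starch") or (spec.invariant_value is not None
                                         and name != "WSC"):
        if spec.invariant_value is None:
            raise ValueError(f"{name} requires an invariant_value")
        base = pd.Series(spec.invariant_value, index=dates)
    elif name == "sucrose":
        weighted = integrate_carryover(daily, n, lam)
        base = weighted.reindex(dates) + spec.offset_vs_assimilates
    elif name == "WSC":
        weighted = integrate_carryover(daily, n, lam)
        sugar = weighted.reindex(dates)
        base = (spec.pinitol_share * spec.pinitol_value
                + (1.0 - spec.pinitol_share) * sugar
                + spec.offset_vs_assimilates)
    elif name == "TOM":
        if spec.growth_window is None:
            raise ValueError("TOM requires a growth_window")
        g0, g1 = map(pd.Timestamp, spec.growth_window)
        weighted = integrate_carryover(daily, n, lam)
        in_growth = weighted[(weighted.index >= g0) & (weighted.index <= g1)]
        if in_growth.empty:
            raise ValueError("daily signal does not cover the growth window")
        frozen = float(in_growth.mean())
        vals = weighted.reindex(dates)
        vals[dates > g1] = frozen
        vals[dates < g0] = float(in_growth.iloc[0])
        base = vals + spec.offset_vs_assimilates
    else:
        raise ValueError(f"unknown pool {name!r}")

    if base.isna().any():
        raise ValueError("sampling dates outside the generated daily signal")
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, len(base))
    base.name = f"{name}_{spec.generation}"
    return base


def default_pool_specs() -> dict[tuple[str, str], PoolMixingSpec]:
    """Paper-season pool structure for both needle generations.

    Sucrose carries the (n=4, λ=0.8) assimilate memory; pinitol and starch
    are invariant; WSC mixes 40 % pinitol (-31 ‰) with the sugar signal
    (0N enriched by the stable 0.6 ‰ offset); TOM in 0N tracks
    assimilates only during needle growth, while 1N TOM is invariant.
    Noise defaults are the analytical precisions of the respective
    methods (0.24 ‰ sucrose, 0.19 ‰ pinitol, 0.1 ‰ bulk).
    """
    growth = ("2018-05-20", "2018-07-10")
    return {
        ("sucrose", "1N"): PoolMixingSpec("sucrose", "1N", 4, 0.8, noise_sd=0.24),
        ("sucrose", "0N"): PoolMixingSpec("sucrose", "0N", 4, 0.8, noise_sd=0.24),
        ("pinitol", "1N"): PoolMixingSpec("pinitol", "1N", invariant_value=-31.0,
                                          noise_sd=0.19),
        ("pinitol", "0N"): PoolMixingSpec("pinitol", "0N", invariant_value=-30.1,
                                          noise_sd=0.19),
        ("WSC", "1N"): PoolMixingSpec("WSC", "1N", 4, 0.8, pinitol_share=0.4,
                                      pinitol_value=-31.0, noise_sd=0.1),
        ("WSC", "0N"): PoolMixingSpec("WSC", "0N", 4, 0.8, pinitol_share=0.4,
                                      pinitol_value=-31.0, noise_sd=0.1,
                                      offset_vs_assimilates=0.6),
        ("starch", "1N"): PoolMixingSpec("starch", "1N", invariant_value=-25.5,
                                         noise_sd=0.1),
        ("starch", "0N"): PoolMixingSpec("starch", "0N", invariant_value=-25.0,
                                         noise_sd=0.1),
        ("TOM", "1N"): PoolMixingSpec("TOM", "1N", invariant_value=-29.6,
                                      noise_sd=0.1),
        ("TOM", "0N"): PoolMixingSpec("TOM", "0N", 4, 0.8, growth_window=growth,
                                      noise_sd=0.1, offset_vs_assimilates=-1.3),
    }


def default_sampling_dates(config: SeasonConfig, every_days: int = 8,
                           skip_first_days: int = 13) -> pd.DatetimeIndex:
    """Roughly-weekly needle sampling dates (20 over the default season)."""
    start = pd.Timestamp(config.start_date) + pd.Timedelta(days=skip_first_days)
    end = pd.Timestamp(config.end_date) - pd.Timedelta(days=1)
    return pd.date_range(start, end, freq=f"{every_days}D").normalize()
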