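"""End-to-end orchestration: simulate → fluxes → model → iwue → carryover.

Every stage reads and writes the CSV contracts in :mod:`pinedisc.io`,
logs its record counts to stderr, and can also be driven individually
from the command line.  The full run on synthetic data reproduces the
analysis chain: chamber-derived and modeled assimilate δ13C, iWUE from
gas exchange and from pool δ13C, and the carry-over correlation surface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .carryover import combine_generations, grid_search, integrate_carryover
from .chamber import (flux_weighted_daytime_mean, fluxes_to_frame,
                      process_trace, qc_filter)
from .discrimination import fit_respiration, model_delta_series
from .iwue import (compare_iwue, correct_wsc_for_pinitol, delta_from_pool,
                   iwue_gas, iwue_iso_complex, iwue_iso_simple)
from .meteo import in_daytime_window
from .params import ChamberSpec, DiscriminationParams, RespirationParams
from .synthetic import (PhysiologyConfig, SeasonConfig, daily_assimilate_signal,
                        default_pool_specs, default_sampling_dates,
                        generate_closure_traces, generate_environment,
                        generate_gas_exchange, generate_pool_series)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config object governs every stage."""

    season: SeasonConfig = field(default_factory=SeasonConfig)
    physiology: PhysiologyConfig = field(default_factory=PhysiologyConfig)
    params: DiscriminationParams = field(default_factory=DiscriminationParams)
    resp_truth: RespirationParams = field(default_factory=RespirationParams)
    chamber: ChamberSpec = field(default_factory=ChamberSpec)
    schedule_minutes: int = 120
    trace_noise_sd: float = 0.0        # ppm on the CO2 channels
    qc_min_co2_flux: float = 0.5       # µmol m-2 s-1
    qc_max_rh: float = 75.0            # %
    carryover_n: int = 4               # applied to iWUE_gas for comparison
    carryover_lambda: float = 0.8
    pool_sampling_every_days: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.qc_min_co2_flux <= 0 or self.qc_max_rh <= 0:
            raise ValueError("QC thresholds must be positive")


def _seeded(cfg: PipelineConfig, offset: int) -> int:
    return (cfg.rng_seed * 1000 + offset) % (2**31 - 1)


def simulate(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Generate the synthetic season (env, gas exchange, traces, pools)."""
    season = replace(cfg.season, rng_seed=_seeded(cfg, 1))
    env = generate_environment(season)
    gasex = generate_gas_exchange(env, cfg.physiology, cfg.params, cfg.resp_truth)
    traces = generate_closure_traces(
        gasex, env, chamber=cfg.chamber, schedule_minutes=cfg.schedule_minutes,
        noise_sd=cfg.trace_noise_sd, rng_seed=_seeded(cfg, 2),
        delta13c_respired=cfg.physiology.delta13c_respired)
    log.info("simulate: %d env records, %d closures", len(env), len(traces))

    daily = daily_assimilate_signal(gasex, season.sunrise_hour, season.sunset_hour)
    dates = default_sampling_dates(season, cfg.pool_sampling_every_days)
    rng = np.random.default_rng(_seeded(cfg, 3))
    rows = []
    for (pool, gen), spec in default_pool_specs().items():
        series = generate_pool_series(daily, spec, dates, rng)
        for date, val in series.items():
            rows.append({"date": date, "pool": pool, "generation": gen,
                         "delta13c_permil": val})
    pools = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        pio.write_table(env, out / "env.csv")
        pio.write_table(gasex, out / "gasex.csv")
        pio.write_table(pools, out / "pools.csv")
        for tr in traces:
            pio.write_trace(tr, out / "traces")
    return {"env": env, "gasex": gasex, "traces": traces, "pools": pools,
            "daily_truth": daily}


def estimate_fluxes(traces, cfg: PipelineConfig,
                    out_dir: str | Path | None = None) -> pd.DataFrame:
    """Fit every closure and apply QC."""
    records = [process_trace(tr) for tr in traces]
    fluxes = qc_filter(fluxes_to_frame(records),
                       min_co2_flux=cfg.qc_min_co2_flux, max_rh=cfg.qc_max_rh)
    log.info("fluxes: %d closures, %d pass CO2 QC, %d pass H2O QC",
             len(fluxes), int(fluxes["qc_co2_pass"].sum()),
             int(fluxes["qc_h2o_pass"].sum()))
    if out_dir is not None:
        pio.write_table(fluxes.drop(columns=[c for c in fluxes.columns
                                             if c.startswith("rmse_")]),
                        Path(out_dir) / "fluxes.csv")
    return fluxes


def fit_night_respiration(fluxes: pd.DataFrame, env: pd.DataFrame
                          ) -> RespirationParams:
    """Respiration temperature response from night-time closure fluxes."""
    df = pd.merge(fluxes, env[["timestamp", "par"]], on="timestamp", how="inner")
    night = df[(df["par"] == 0) & (df["f_co2"] < 0)]
    resp, rmse = fit_respiration(night["t_chamber_c"].to_numpy(),
                                 (-night["f_co2"]).to_numpy())
    log.info("respiration fit: R_d0=%.3f, H_alpha=%.0f (rmse %.3g, n=%d)",
             resp.r_d0, resp.h_alpha, rmse, len(night))
    return resp


def delta_series(fluxes: pd.DataFrame, env: pd.DataFrame, cfg: PipelineConfig,
                 resp: RespirationParams,
                 out_dir: str | Path | None = None) -> pd.DataFrame:
    """Daily flux-weighted δ13C_A from the chamber and from the model."""
    ok = fluxes[fluxes["qc_co2_pass"]]
    if ok.empty:
        log.warning("delta_series: no closures pass the CO2-flux QC; "
                    "chamber series is empty")
        picarro = pd.Series(dtype=float)
    else:
        ts = pd.DatetimeIndex(ok["timestamp"])
        mask = in_daytime_window(ts, cfg.season.sunrise_hour,
                                 cfg.season.sunset_hour)
        picarro = flux_weighted_daytime_mean(
            pd.Series(ok["delta13c_a_picarro"].to_numpy(), index=ts),
            pd.Series(ok["f_co2"].to_numpy(), index=ts), mask)

    gasex_like = ok.rename(columns={"f_co2": "a", "f_h2o": "e"})[
        ["timestamp", "a", "e"]].dropna()
    if gasex_like.empty:
        log.warning("delta_series: no QC-passing fluxes with transpiration; "
                    "model series is empty")
        model = pd.Series(dtype=float)
    else:
        model = model_delta_series(gasex_like, env, cfg.params, resp,
                                   cfg.season.sunrise_hour,
                                   cfg.season.sunset_hour)
    out = pd.DataFrame({"date": picarro.index.union(model.index)})
    out["delta13c_a_picarro"] = picarro.reindex(out["date"]).to_numpy()
    out["delta13c_a_model"] = model.reindex(out["date"]).to_numpy()
    if out_dir is not None:
        pio.write_table(out, Path(out_dir) / "model_delta.csv")
    return out


def daily_iwue_gas(fluxes: pd.DataFrame, env: pd.DataFrame,
                   cfg: PipelineConfig) -> pd.Series:
    """Daily flux-weighted daytime mean iWUE from the chamber fluxes."""
    df = pd.merge(fluxes[fluxes["qc_co2_pass"]], env, on="timestamp",
                  how="inner").dropna(subset=["f_h2o"])
    df = df[(df["f_co2"] > 0) & (df["f_h2o"] > 0) & (df["es"] > df["ea"])]
    if df.empty:
        raise ValueError("no QC-passing daytime fluxes for iWUE_gas")
    _, iwue = iwue_gas(df["f_co2"].to_numpy(), df["f_h2o"].to_numpy(),
                       df["es"].to_numpy(), df["ea"].to_numpy(),
                       df["p_amb"].to_numpy())
    ts = pd.DatetimeIndex(df["timestamp"])
    mask = in_daytime_window(ts, cfg.season.sunrise_hour, cfg.season.sunset_hour)
    return flux_weighted_daytime_mean(pd.Series(iwue, index=ts),
                                      pd.Series(df["f_co2"].to_numpy(), index=ts),
                                      mask)


def _fill_daily_gaps(daily: pd.Series, what: str) -> pd.Series:
    """Time-interpolate interior gaps of a daily series (QC can void whole
    days; the carry-over window needs contiguous daily coverage)."""
    full = daily.reindex(pd.date_range(daily.index.min(), daily.index.max(),
                                       freq="D"))
    n_gap = int(full.isna().sum())
    if n_gap:
        log.info("%s: interpolating %d missing day(s) before carry-over "
                 "integration", what, n_gap)
    return full.interpolate(method="time")


def _pool_series(pools: pd.DataFrame, pool: str, gen: str) -> pd.Series:
    sel = pools[(pools["pool"] == pool) & (pools["generation"] == gen)]
    return pd.Series(sel["delta13c_permil"].to_numpy(),
                     index=pd.DatetimeIndex(sel["date"]).normalize())


def iwue_stage(pools: pd.DataFrame, fluxes: pd.DataFrame, env: pd.DataFrame,
               cfg: PipelineConfig, resp: RespirationParams,
               out_dir: str | Path | None = None) -> pd.DataFrame:
    """Pool-δ13C iWUE inversions vs carry-over-integrated iWUE_gas.

    Inversion inputs (ca, δ13C_air, Tl, A) are daily daytime means from
    the environmental series and the chamber fluxes, per the convention
    that ca and δ13C_air are the pre-closure ambient values.
    """
    iwue_g = _fill_daily_gaps(daily_iwue_gas(fluxes, env, cfg), "iwue_gas")
    iwue_g_int = integrate_carryover(iwue_g, cfg.carryover_n, cfg.carryover_lambda)

    ts = pd.DatetimeIndex(env["timestamp"])
    daymask = in_daytime_window(ts, cfg.season.sunrise_hour, cfg.season.sunset_hour)
    env_day = env[daymask].copy()
    env_daily = env_day.groupby(pd.DatetimeIndex(env_day["timestamp"]).normalize())[
        ["ca", "delta13c_air", "t_air"]].mean()
    okf = fluxes[fluxes["qc_co2_pass"]]
    tsf = pd.DatetimeIndex(okf["timestamp"])
    fmask = in_daytime_window(tsf, cfg.season.sunrise_hour, cfg.season.sunset_hour)
    a_daily = pd.Series(okf["f_co2"].to_numpy(), index=tsf)[fmask]
    a_daily = a_daily.groupby(a_daily.index.normalize()).mean()

    sucrose = combine_generations(_pool_series(pools, "sucrose", "0N"),
                                  _pool_series(pools, "sucrose", "1N"), "sucrose")
    wsc = combine_generations(_pool_series(pools, "WSC", "0N"),
                              _pool_series(pools, "WSC", "1N"), "WSC")
    wsc_corr = pd.Series(
        correct_wsc_for_pinitol(wsc.to_numpy(), 0.4, -31.0), index=wsc.index)

    rows = []
    for name, series in [("sucrose", sucrose), ("WSC_pinitol_corrected", wsc_corr)]:
        dates = series.index.intersection(env_daily.index).intersection(
            a_daily.index)
        for date in dates:
            ca = float(env_daily.loc[date, "ca"])
            d_air = float(env_daily.loc[date, "delta13c_air"])
            tl = float(env_daily.loc[date, "t_air"])
            a = float(a_daily.loc[date])
            delta_cap = delta_from_pool(float(series.loc[date]), d_air)
            rows.append({
                "date": date,
                "iwue_gas": float(iwue_g_int.loc[date]) if date in iwue_g_int.index
                            else np.nan,
                "iwue_iso_complex": iwue_iso_complex(delta_cap, ca, a, tl,
                                                     cfg.params, resp),
                "iwue_iso_simple": iwue_iso_simple(delta_cap, ca, cfg.params),
                "source_pool": name,
            })
    out = pd.DataFrame(rows)
    if out_dir is not None:
        pio.write_table(out, Path(out_dir) / "iwue.csv")
    return out


def carryover_stage(pools: pd.DataFrame, driver: pd.Series,
                    cfg: PipelineConfig,
                    out_dir: str | Path | None = None):
    """Grid-search the sucrose carry-over against the modeled δ13C driver."""
    if driver.empty:
        raise ValueError("empty carry-over driver series")
    sucrose = combine_generations(_pool_series(pools, "sucrose", "0N"),
                                  _pool_series(pools, "sucrose", "1N"), "sucrose")
    surface = grid_search(sucrose, _fill_daily_gaps(driver, "carryover driver"))
    log.info("carryover: best (n=%d, λ=%.1f), ρ=%.3f (p=%.2g)",
             surface.best_n, surface.best_lam, surface.best_rho, surface.best_p)
    if out_dir is not None:
        pio.write_table(surface.table, Path(out_dir) / "surface.csv")
    return surface


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order and write the report bundle."""
    out = Path(out_dir)
    sim = simulate(cfg, out)
    fluxes = estimate_fluxes(sim["traces"], cfg, out)
    resp = fit_night_respiration(fluxes, sim["env"])
    deltas = delta_series(fluxes, sim["env"], cfg, resp, out)
    try:
        iwue_tab = iwue_stage(sim["pools"], fluxes, sim["env"], cfg, resp, out)
    except ValueError as err:
        log.warning("iwue stage skipped: %s", err)
        iwue_tab = pd.DataFrame(columns=["date", "iwue_gas", "iwue_iso_complex",
                                         "iwue_iso_simple", "source_pool"])
    model_daily = pd.Series(deltas["delta13c_a_model"].to_numpy(),
                            index=pd.DatetimeIndex(deltas["date"])).dropna()
    try:
        surface = carryover_stage(sim["pools"], model_daily, cfg, out)
    except ValueError as err:
        log.warning("carryover stage skipped: %s", err)
        surface = None

    suc = iwue_tab[iwue_tab["source_pool"] == "sucrose"].dropna(
        subset=["iwue_gas", "iwue_iso_complex"])
    comparison = (compare_iwue(suc["iwue_iso_complex"], suc["iwue_gas"])
                  if len(suc) >= 3 else None)
    report = {
        "n_closures": int(len(fluxes)),
        "n_qc_co2_fail": int((~fluxes["qc_co2_pass"]).sum()),
        "n_qc_h2o_fail": int((~fluxes["qc_h2o_pass"]).sum()),
        "fitted_r_d0": round(resp.r_d0, 3),
        "fitted_h_alpha": round(resp.h_alpha, 1),
        "delta13c_a_picarro_mean": round(float(
            deltas["delta13c_a_picarro"].mean()), 1)
                                   if deltas["delta13c_a_picarro"].notna().any()
                                   else None,
        "delta13c_a_model_mean": round(float(
            deltas["delta13c_a_model"].mean()), 1)
                                 if deltas["delta13c_a_model"].notna().any()
                                 else None,
    }
    if surface is not None:
        report.update({
            "carryover_best_n": surface.best_n,
            "carryover_best_lambda": surface.best_lam,
            "carryover_best_rho": round(surface.best_rho, 2),
        })
    if comparison is not None:
        report.update({
            "iwue_sucrose_vs_gas_pearson_r": round(comparison.pearson_r, 2),
            "iwue_sucrose_vs_gas_mean_offset_ppm": round(comparison.mean_offset),
            "iwue_gas_mean_ppm": round(float(suc["iwue_gas"].mean())),
            "iwue_iso_complex_mean_ppm": round(float(
                suc["iwue_iso_complex"].mean())),
        })
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("report written to %s", out / "report.json")
    return {"config": cfg, "report": report, "fluxes": fluxes, "deltas": deltas,
            "iwue": iwue_tab, "surface": surface, "resp": resp, **sim}
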