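import numpy as np
import pandas as pd
import pytest

from pinedisc import synthetic as syn
from pinedisc.chamber import fit_closure_flux
from pinedisc.discrimination import (mitochondrial_respiration,
                                     model_discrimination)
from pinedisc.params import DiscriminationParams, RespirationParams
from conftest import make_trace


class TestEnvironment:
    def test_deterministic_given_seed(self, short_season):
        cfg, env, _ = short_season
        again = syn.generate_environment(cfg)
        pd.testing.assert_frame_equal(env, again)

    def test_physical_invariants(self, short_season):
        _, env, _ = short_season
        assert env["rh"].between(0, 100).all()
        assert (env["es"] >= env["ea"]).all()
        assert np.allclose(env["vpd"], env["es"] - env["ea"])
        assert (env["par"] >= 0).all()
        night = ~env["timestamp"].dt.hour.between(4, 21)
        assert (env.loc[night, "par"] == 0).all()

    def test_dry_period_reaches_floor(self):
        cfg = syn.SeasonConfig(start_date="2018-08-01", end_date="2018-09-20",
                               timestep_minutes=120,
                               dry_period=("2018-08-16", "2018-09-10"),
                               rng_seed=1)
        env = syn.generate_environment(cfg)
        in_dry = env[(env["timestamp"] >= "2018-09-08")
                     & (env["timestamp"] <= "2018-09-10")]
        assert in_dry["soil_moisture"].min() <= cfg.soil_moisture_floor + 0.02

    def test_invalid_timestep_rejected(self):
        with pytest.raises(ValueError):
            syn.SeasonConfig(timestep_minutes=-10)
        with pytest.raises(ValueError):
            syn.SeasonConfig(timestep_minutes=7)  # does not divide a day


class TestGasExchange:
    def test_night_flux_is_respiratory_efflux(self, short_season, default_resp):
        _, env, gasex = short_season
        night = env["par"].to_numpy() == 0
        expected = -mitochondrial_respiration(env["t_air"].to_numpy()[night],
                                              default_resp)
        assert np.allclose(gasex["a"].to_numpy()[night], expected)

    def test_ci_follows_scheduled_iwue(self, short_season):
        _, env, gasex = short_season
        day = env["par"].to_numpy() > 0
        ci = gasex["ci"].to_numpy()[day]
        iwue = gasex["iwue_true"].to_numpy()[day]
        assert np.allclose(ci, env["ca"].to_numpy()[day] - 1.6 * iwue)

    def test_truth_self_consistency(self, short_season, default_params,
                                    default_resp):
        """Re-evaluating the discrimination model on the stored fields
        reproduces the stored truth to numerical precision."""
        _, env, gasex = short_season
        day = env["par"].to_numpy() > 0
        redone = model_discrimination(
            gasex["a"].to_numpy()[day], env["ca"].to_numpy()[day],
            gasex["ci"].to_numpy()[day], gasex["t_leaf"].to_numpy()[day],
            default_params, default_resp)
        assert np.max(np.abs(redone - gasex["delta_cap_true"].to_numpy()[day])) \
            < 1e-9

    def test_schedule_below_compensation_point_rejected(self, short_season):
        cfg, env, _ = short_season
        phys = syn.PhysiologyConfig(iwue_min=250.0, iwue_max=260.0)
        with pytest.raises(ValueError, match="Γ|compensation|ci"):
            syn.generate_gas_exchange(env, phys)


class TestClosureTraces:
    def test_zero_flux_noiseless_trace_is_ambient(self):
        tr = make_trace(a=0.0, e=0.0)
        assert np.allclose(tr.co2, tr.ca_ambient)
        assert np.allclose(tr.c12 + tr.c13, tr.ca_ambient)

    def test_noiseless_trace_refit_recovers_flux(self):
        tr = make_trace(a=5.0)
        fit = fit_closure_flux(tr, "co2")
        assert abs(fit.flux - 5.0) / 5.0 < 1e-3  # < 0.1 %

    def test_trace_determinism(self, short_season):
        cfg, env, gasex = short_season
        t1 = syn.generate_closure_traces(gasex, env, schedule_minutes=120,
                                         noise_sd=0.3, rng_seed=5)
        t2 = syn.generate_closure_traces(gasex, env, schedule_minutes=120,
                                         noise_sd=0.3, rng_seed=5)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.c12, b.c12)
            assert np.array_equal(a.h2o, b.h2o)


class TestPoolSeries:
    def _daily(self, values, start="2018-06-01"):
        return pd.Series(values, index=pd.date_range(start, periods=len(values)))

    def test_no_memory_zero_noise_equals_daily_signal(self):
        d = self._daily(np.linspace(-28, -25, 10))
        spec = syn.PoolMixingSpec("sucrose", "1N", carryover_days=0,
                                  previous_day_weight=0.8)
        out = syn.generate_pool_series(d, spec, d.index[2:])
        assert np.allclose(out.to_numpy(), d.iloc[2:].to_numpy())

    def test_invariant_pinitol(self):
        d = self._daily(np.linspace(-28, -25, 10))
        spec = syn.PoolMixingSpec("pinitol", "1N", invariant_value=-31.0)
        out = syn.generate_pool_series(d, spec, d.index[5:])
        assert np.allclose(out.to_numpy(), -31.0)

    def test_wsc_linear_mixture(self):
        d = self._daily(np.full(10, -26.4))
        spec = syn.PoolMixingSpec("WSC", "1N", carryover_days=2,
                                  previous_day_weight=0.8, pinitol_share=0.4,
                                  pinitol_value=-31.0)
        out = syn.generate_pool_series(d, spec, d.index[5:])
        assert np.allclose(out.to_numpy(), 0.4 * -31.0 + 0.6 * -26.4)

    def test_tom_freezes_after_growth(self):
        d = self._daily(np.linspace(-28, -24, 30))
        spec = syn.PoolMixingSpec("TOM", "0N", carryover_days=0,
                                  previous_day_weight=1.0,
                                  growth_window=("2018-06-05", "2018-06-15"))
        out = syn.generate_pool_series(d, spec, d.index[5:])
        after = out[out.index > pd.Timestamp("2018-06-15")]
        assert after.nunique() == 1  # frozen at the growth-window mean

    def test_missing_lookback_coverage_rejected(self):
        d = self._daily(np.linspace(-28, -25, 5))
        spec = syn.PoolMixingSpec("sucrose", "1N", carryover_days=4,
                                  previous_day_weight=0.8)
        with pytest.raises(ValueError, match="look-back"):
            syn.generate_pool_series(d, spec, d.index[:2])

    def test_pool_noise_deterministic_with_rng(self):
        d = self._daily(np.linspace(-28, -25, 10))
        spec = syn.PoolMixingSpec("sucrose", "1N", 2, 0.8, noise_sd=0.24)
        a = syn.generate_pool_series(d, spec, d.index[4:],
                                     np.random.default_rng(3))
        b = syn.generate_pool_series(d, spec, d.index[4:],
                                     np.random.default_rng(3))
        assert np.array_equal(a.to_numpy(), b.to_numpy())
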