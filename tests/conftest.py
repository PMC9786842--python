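import numpy as np
import pandas as pd
import pytest

from pinedisc.chamber import ClosureTrace
from pinedisc.params import ChamberSpec, DiscriminationParams, RespirationParams
from pinedisc.synthetic import (PhysiologyConfig, SeasonConfig,
                                generate_closure_trace, generate_environment,
                                generate_gas_exchange)


@pytest.fixture(scope="session")
def default_params():
    return DiscriminationParams()


@pytest.fixture(scope="session")
def default_resp():
    return RespirationParams(r_d0=0.8, h_alpha=40_000.0)


@pytest.fixture(scope="session")
def short_season():
    """Three rain-free June days at 30 min; shared by generator tests."""
    cfg = SeasonConfig(start_date="2018-06-01", end_date="2018-06-04",
                       timestep_minutes=30, dry_period=None,
                       rain_probability=0.0, rng_seed=11)
    env = generate_environment(cfg)
    gasex = generate_gas_exchange(env)
    return cfg, env, gasex


def make_trace(a=5.0, e=1.0, delta_a=-26.68, noise_sd=0.0, rng=None,
               chamber=None, t_air=20.0, rh=60.0):
    """One synthetic closure trace from a fabricated steady record."""
    truth = pd.Series({"timestamp": pd.Timestamp("2018-06-15 12:00"),
                       "a": a, "e": e, "delta13c_a_true": delta_a})
    env = pd.Series({"ca": 405.0, "delta13c_air": -8.5, "t_air": t_air,
                     "rh": rh, "p_amb": 98.8})
    return generate_closure_trace(truth, env,
                                  chamber=chamber or ChamberSpec(),
                                  noise_sd=noise_sd,
                                  rng=rng or np.random.default_rng(0),
                                  closure_id="fixture")
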