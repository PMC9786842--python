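import numpy as np
import pandas as pd
import pytest

from pinedisc import chamber
from pinedisc.params import R_VPDB, ChamberSpec
from conftest import make_trace


class TestClosureFit:
    def test_constant_trace_gives_zero_flux_with_flag(self):
        tr = make_trace(a=0.0, e=0.0)
        fit = chamber.fit_closure_flux(tr, "co2")
        assert fit.flat
        assert fit.flux == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("species, truth_attr", [
        ("co2", "a"), ("c12", None), ("h2o", None),
    ])
    def test_noiseless_round_trip(self, species, truth_attr):
        tr = make_trace(a=5.0, e=1.0)
        fit = chamber.fit_closure_flux(tr, species)
        if species == "co2":
            assert fit.flux == pytest.approx(5.0, rel=1e-6)
        elif species == "c12":
            # 12CO2 share of the net flux at the trace's delta
            from pinedisc.params import delta_to_ratio
            f12_true = 5.0 / (1.0 + delta_to_ratio(-26.68))
            assert fit.flux == pytest.approx(f12_true, rel=1e-6)
        else:
            assert -fit.flux / 1000.0 == pytest.approx(1.0, rel=1e-6)

    def test_uptake_trace_strictly_decreasing_toward_deficit(self):
        tr = make_trace(a=5.0)
        assert np.all(np.diff(tr.co2) < 0)
        n_flow = chamber.molar_flow(tr.chamber.sample_flow_dm3_min,
                                    tr.p_amb_kpa, tr.t_chamber_c)
        c_inf = tr.ca_ambient - 5.0 * tr.chamber.needle_area_m2 / n_flow
        assert np.all(tr.co2 > c_inf)

    def test_noisy_recovery_unbiased(self):
        rng = np.random.default_rng(7)
        est = []
        for _ in range(200):
            tr = make_trace(a=5.0, noise_sd=0.2, rng=rng)
            est.append(chamber.fit_closure_flux(tr, "co2").flux)
        assert np.mean(est) == pytest.approx(5.0, rel=0.02)

    def test_too_few_points_rejected(self):
        tr = make_trace()
        short = chamber.ClosureTrace(
            closure_id="x", timestamp=tr.timestamp,
            t_fast=tr.t_fast[:8], c12=tr.c12[:8], c13=tr.c13[:8],
            t_slow=tr.t_slow[:2], co2=tr.co2[:2], h2o=tr.h2o[:2],
            chamber=tr.chamber, ca_ambient=tr.ca_ambient,
            delta13c_air=tr.delta13c_air, t_chamber_c=tr.t_chamber_c,
            rh_chamber=tr.rh_chamber, p_amb_kpa=tr.p_amb_kpa)
        with pytest.raises(ValueError, match="6 points"):
            chamber.fit_closure_flux(short, "co2")

    def test_bad_chamber_geometry_rejected(self):
        with pytest.raises(ValueError):
            ChamberSpec(volume_dm3=-1.0)


class TestDeltaFromFluxes:
    def test_vpdb_ratio_is_zero_permil(self):
        assert chamber.delta13c_from_fluxes(R_VPDB * 5.0, 5.0) == pytest.approx(0.0)

    def test_depleted_ratio(self):
        assert chamber.delta13c_from_fluxes(0.97 * R_VPDB * 2.0, 2.0) == \
            pytest.approx(-30.0, abs=1e-9)

    def test_common_rescaling_invariance(self):
        d1 = chamber.delta13c_from_fluxes(0.05, 4.0)
        d2 = chamber.delta13c_from_fluxes(0.05 * 3.7, 4.0 * 3.7)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_nonpositive_f12_rejected(self):
        with pytest.raises(ValueError):
            chamber.delta13c_from_fluxes(0.05, 0.0)

    def test_round_trip_through_trace(self):
        rec = chamber.process_trace(make_trace(a=5.0, e=1.0, delta_a=-26.68))
        assert rec.delta13c_a_picarro == pytest.approx(-26.68, abs=0.01)


class TestQC:
    def _records(self, f_co2, rh=60.0):
        return pd.DataFrame({
            "closure_id": [f"c{i}" for i in range(len(f_co2))],
            "f_co2": f_co2,
            "f_h2o": 1.0,
            "delta13c_a_picarro": -26.0,
            "rh_chamber": rh,
            "qc_co2_pass": True, "qc_h2o_pass": True,
        })

    def test_strict_threshold_boundary(self):
        out = chamber.qc_filter(self._records([0.49, 0.50]))
        assert np.isnan(out["delta13c_a_picarro"].iloc[0])
        assert out["delta13c_a_picarro"].iloc[1] == pytest.approx(-26.0)

    def test_counts_and_value_preservation(self):
        f = [0.1, 0.2, 0.3, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        out = chamber.qc_filter(self._records(f))
        assert out["delta13c_a_picarro"].notna().sum() == 7
        kept = out[out["qc_co2_pass"]]
        assert (kept["delta13c_a_picarro"] == -26.0).all()
        assert (out["f_co2"] == f).all()  # fluxes themselves untouched

    def test_rh_filter_nulls_transpiration_only(self):
        out = chamber.qc_filter(self._records([1.0, 1.0], rh=80.0))
        assert out["f_h2o"].isna().all()
        assert out["delta13c_a_picarro"].notna().all()


class TestFluxWeightedMean:
    def _series(self, vals, weights, hours):
        ts = pd.to_datetime([f"2018-06-01 {h:02d}:00" for h in hours])
        return (pd.Series(vals, index=ts), pd.Series(weights, index=ts),
                np.ones(len(ts), dtype=bool))

    def test_equal_weights_is_arithmetic_mean(self):
        v, w, m = self._series([-25.0, -26.0, -27.0], [2.0, 2.0, 2.0], [10, 12, 14])
        assert chamber.flux_weighted_daytime_mean(v, w, m).iloc[0] == \
            pytest.approx(-26.0)

    def test_weighted_example(self):
        v, w, m = self._series([-25.0, -27.0], [3.0, 1.0], [10, 14])
        assert chamber.flux_weighted_daytime_mean(v, w, m).iloc[0] == \
            pytest.approx(-25.5)

    def test_zero_weight_has_no_influence(self):
        v, w, m = self._series([-25.0, -99.0], [3.0, 0.0], [10, 14])
        assert chamber.flux_weighted_daytime_mean(v, w, m).iloc[0] == \
            pytest.approx(-25.0)

    def test_all_zero_weights_rejected(self):
        v, w, m = self._series([-25.0, -27.0], [0.0, 0.0], [10, 14])
        with pytest.raises(ValueError):
            chamber.flux_weighted_daytime_mean(v, w, m)
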