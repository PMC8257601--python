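"""Flux computation, source partitioning, cumulation, and priming."""

import numpy as np
import pandas as pd
import pytest

from littertrace import respiration, synthetic
from littertrace.respiration import (
    RespirationConfig,
    cumulate,
    interval_flux,
    molar_volume_ml_per_mmol,
    partition_interval,
    priming,
    process_gas_table,
)


@pytest.fixture
def cfg():
    return RespirationConfig(v_headspace_ml=241.0, molar_volume_ml_mmol=24.1, c_bulk_mass_g=1.0)


class TestIntervalFlux:
    def test_hand_evaluated_example(self, cfg):
        # 1 ppm/min, 241 ml headspace, 24.1 ml/mmol -> 0.0072 mg/h
        assert interval_flux(60.0, 60.0, cfg) == pytest.approx(0.0072, rel=1e-12)

    def test_zero_change_zero_flux(self, cfg):
        assert interval_flux(0.0, 30.0, cfg) == 0.0

    def test_linearity_in_headspace_volume(self, cfg):
        double = RespirationConfig(
            v_headspace_ml=482.0, molar_volume_ml_mmol=24.1, c_bulk_mass_g=1.0
        )
        assert interval_flux(60.0, 60.0, double) == pytest.approx(
            2 * interval_flux(60.0, 60.0, cfg)
        )

    def test_negative_duration_rejected(self, cfg):
        with pytest.raises(ValueError):
            interval_flux(10.0, -5.0, cfg)

    def test_negative_change_flagged(self, cfg):
        with pytest.warns(UserWarning, match="leak"):
            interval_flux(-10.0, 60.0, cfg)

    def test_molar_volume_at_21C(self):
        assert molar_volume_ml_per_mmol(21.0) == pytest.approx(24.1, abs=0.05)


class TestPartition:
    def test_endpoints(self, cfg):
        assert partition_interval(cfg.delta_control, cfg) == 0.0
        assert partition_interval(cfg.delta_litter, cfg) == 100.0

    def test_midpoint(self, cfg):
        assert partition_interval(1050.5, cfg) == pytest.approx(50.0, rel=1e-12)

    def test_control_delta_from_paired_controls(self, scenario, gas_bundle):
        # noiseless: control mean equals the configured constant, so
        # the measured-control path gives identical partitioning
        gas, truth = gas_bundle
        cfg = synthetic.respiration_config(scenario, "coarse")
        iv = process_gas_table(gas[gas["texture"] == "coarse"], cfg)
        lit = iv[(iv["treatment"] == "litter") & (iv["microcosm_id"] == "coarse_litter_1")]
        expected = 100 * np.asarray(truth["per_texture"]["coarse"]["litter_fraction"])
        assert np.allclose(lit.sort_values("day")["litter_pct"].to_numpy(), expected, atol=1e-9)


class TestCumulate:
    def test_constant_flux_closed_form(self):
        cfg = RespirationConfig(c_bulk_mass_g=2.0)
        days = [1, 2, 5, 10]
        iv = pd.DataFrame(
            {
                "microcosm_id": "m1",
                "treatment": "litter",
                "texture": "coarse",
                "day": days,
                "flux_mg_h": 0.5,
                "litter_pct": 40.0,
            }
        )
        out = cumulate(iv, cfg)
        # constant rate F: cumulative = F * t / c_bulk
        expect = 0.5 * np.array(days) * 24.0 / 2.0
        assert np.allclose(out["cum_total_mg_gC"], expect, rtol=1e-12)
        assert np.allclose(out["cum_litter_mg_gC"], 0.4 * expect, rtol=1e-12)

    def test_double_exponential_within_trapezoid_error(self):
        # analytic integral of a two-pool source vs trapezoidal cumulation
        cfg = RespirationConfig(c_bulk_mass_g=1.0)
        a1, k1, a2, k2 = 2.0, 0.08, 0.5, 0.002  # mg/d, 1/d
        days = np.arange(1, 96)  # dense grid: trapezoid error is O(h^2)
        rate_h = (a1 * np.exp(-k1 * days) + a2 * np.exp(-k2 * days)) / 24.0
        iv = pd.DataFrame(
            {
                "microcosm_id": "m1",
                "treatment": "litter",
                "texture": "coarse",
                "day": days,
                "flux_mg_h": rate_h,
                "litter_pct": 0.0,
            }
        )
        out = cumulate(iv, cfg)
        analytic = a1 / k1 * (1 - np.exp(-k1 * 95)) + a2 / k2 * (1 - np.exp(-k2 * 95))
        # second-order error bound: h^2/12 * max|f''| * T, h = 1 day
        bound = (1.0 / 12) * (a1 * k1**2 + a2 * k2**2) * 95
        assert abs(out["cum_total_mg_gC"].iloc[-1] - analytic) < bound + 0.05

    def test_conservation_total_equals_litter_plus_soil(self, scenario, gas_bundle):
        gas, _ = gas_bundle
        cfg = synthetic.respiration_config(scenario, "fine")
        out = cumulate(process_gas_table(gas[gas["texture"] == "fine"], cfg), cfg)
        resid = out["cum_total_mg_gC"] - out["cum_litter_mg_gC"] - out["cum_soil_mg_gC"]
        assert np.all(np.abs(resid) <= 1e-9 * np.maximum(out["cum_total_mg_gC"], 1e-30))

    def test_halving_cbulk_doubles_normalised_values(self, scenario, gas_bundle):
        gas, _ = gas_bundle
        sub = gas[gas["microcosm_id"] == "coarse_litter_1"]
        cfg1 = synthetic.respiration_config(scenario, "coarse")
        cfg2 = RespirationConfig(
            v_headspace_ml=cfg1.v_headspace_ml,
            molar_volume_ml_mmol=cfg1.molar_volume_ml_mmol,
            c_bulk_mass_g=cfg1.c_bulk_mass_g / 2,
            delta_litter=cfg1.delta_litter,
            delta_control=cfg1.delta_control,
        )
        out1 = cumulate(process_gas_table(sub, cfg1), cfg1)
        out2 = cumulate(process_gas_table(sub, cfg2), cfg2)
        assert np.allclose(out2["cum_total_mg_gC"], 2 * out1["cum_total_mg_gC"], rtol=1e-12)

    def test_duplicated_days_rejected(self):
        cfg = RespirationConfig()
        iv = pd.DataFrame(
            {
                "microcosm_id": "m1",
                "treatment": "litter",
                "texture": "coarse",
                "day": [1, 1, 2],
                "flux_mg_h": 0.1,
                "litter_pct": 0.0,
            }
        )
        with pytest.raises(ValueError, match="duplicated"):
            cumulate(iv, cfg)


class TestPriming:
    def _series(self, days, soil, total, treatment):
        return pd.DataFrame(
            {
                "microcosm_id": "m",
                "treatment": treatment,
                "texture": "coarse",
                "day": days,
                "cum_soil_mg_gC": soil,
                "cum_total_mg_gC": total,
            }
        )

    def test_identical_series_zero_priming(self):
        lit = self._series([10, 95], [30.0, 66.1], [40.0, 90.0], "litter")
        ctl = self._series([10, 95], [30.0, 66.1], [30.0, 66.1], "control")
        res = priming(lit, ctl)
        assert res.total_priming_mg_gC == pytest.approx(0.0, abs=1e-12)

    def test_reported_native_minus_control(self):
        # native (soil-derived) 89.4 vs control 66.1 -> priming 23.3
        lit = self._series([95], [89.4], [129.8], "litter")
        ctl = self._series([95], [66.1], [66.1], "control")
        assert priming(lit, ctl).total_priming_mg_gC == pytest.approx(23.3, abs=1e-9)

    def test_mismatched_days_rejected(self):
        lit = self._series([10, 95], [1.0, 2.0], [1.0, 2.0], "litter")
        ctl = self._series([10, 80], [1.0, 2.0], [1.0, 2.0], "control")
        with pytest.raises(ValueError, match="different days"):
            priming(lit, ctl)

    def test_unity_priming_multiplier_gives_zero(self):
        cfg = synthetic.ScenarioConfig(priming_multiplier={"coarse": 1.0, "fine": 1.0})
        gas, _ = synthetic.gen_respiration(cfg)
        rc = synthetic.respiration_config(cfg, "coarse")
        out = cumulate(process_gas_table(gas[gas["texture"] == "coarse"], rc), rc)
        res = priming(out[out["treatment"] == "litter"], out[out["treatment"] == "control"])
        assert abs(res.total_priming_mg_gC) < 1e-9

    def test_injected_priming_recovered(self, scenario, gas_bundle):
        gas, truth = gas_bundle
        for texture in ("coarse", "fine"):
            rc = synthetic.respiration_config(scenario, texture)
            out = cumulate(process_gas_table(gas[gas["texture"] == texture], rc), rc)
            res = priming(out[out["treatment"] == "litter"], out[out["treatment"] == "control"])
            true_traj = np.asarray(truth["per_texture"][texture]["priming_mg_gC"])
            assert np.allclose(res.priming_mg_gC, true_traj, atol=1e-6)
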