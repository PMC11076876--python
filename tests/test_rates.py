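"""Rate engine: HRT, conversion rates, CO2 and H2 gas accounting."""


import numpy as np
import pytest

from ceflux.compounds import gas_volume_to_moles
from ceflux.rates import (
    CO2Equilibrium,
    co2_utilization,
    dissolved_co2_effluent,
    h2_output,
    hydraulic_retention_time,
    liquid_conversion_rates,
)
from ceflux.timeseries import FeedDefinition, Sample


class TestHRT:
    def test_study_flows(self):
        # 24 * 1000 / (522 + 39) = 42.78 h, the stable phase-IV residence time
        assert hydraulic_retention_time(1.0, 522.0, 39.0) == pytest.approx(
            42.78, abs=0.01
        )

    def test_feed_only(self):
        assert hydraulic_retention_time(1.0, 500.0) == pytest.approx(48.0)

    def test_scale_invariance(self):
        assert hydraulic_retention_time(2.0, 1044.0, 78.0) == pytest.approx(
            hydraulic_retention_time(1.0, 522.0, 39.0)
        )

    def test_zero_flow_undefined(self):
        with pytest.raises(ValueError, match="batch"):
            hydraulic_retention_time(1.0, 0.0, 0.0)


def _sample(t, broth, feed_flow=500.0, base_flow=0.0):
    return Sample(time=t, broth=dict(broth), feed_flow=feed_flow, base_flow=base_flow)


class TestLiquidConversionRates:
    FEED = FeedDefinition(composition={"ethanol": 1200.0, "acetate": 50.0})

    def test_steady_state_at_feed_is_zero(self):
        s0 = _sample(0.0, {"ethanol": 1200.0, "acetate": 50.0})
        s1 = _sample(1.0, {"ethanol": 1200.0, "acetate": 50.0})
        rates = liquid_conversion_rates(s0, s1, self.FEED, 1.0)
        assert all(abs(r) < 1e-12 for r in rates.values())

    def test_net_consumption(self):
        # 900 mCM in the broth against 1200 mCM fed at 0.5 L/d: -150 mCmol/L/d
        s0 = _sample(0.0, {"ethanol": 900.0})
        s1 = _sample(1.0, {"ethanol": 900.0})
        rates = liquid_conversion_rates(s0, s1, self.FEED, 1.0)
        assert rates["ethanol"] == pytest.approx(-150.0)

    def test_inert_tracer_washout_reads_as_no_reaction(self):
        """CSTR washout of a non-reacting tracer must yield ~zero rate."""
        feed = FeedDefinition(composition={"acetate": 0.0})
        v, q = 1.0, 0.5  # tau = 2 d
        times = np.arange(0.0, 10.5, 0.5)
        conc = 100.0 * np.exp(-q * times / v)
        samples = [_sample(t, {"acetate": c}) for t, c in zip(times, conc)]
        scale = 100.0 * q / v  # initial flow-term magnitude
        for s0, s1 in zip(samples, samples[1:]):
            r = liquid_conversion_rates(s0, s1, feed, v)["acetate"]
            assert abs(r) < 0.005 * scale

    def test_negative_interval_rejected(self):
        s0 = _sample(1.0, {"ethanol": 900.0})
        s1 = _sample(0.5, {"ethanol": 900.0})
        with pytest.raises(ValueError):
            liquid_conversion_rates(s0, s1, self.FEED, 1.0)


class TestCO2Utilization:
    def test_in_equals_out(self):
        assert co2_utilization(100.0, 100.0, 0.0) == 0.0

    def test_arithmetic(self):
        # 6.0 vs 4.0 NmL/L/min and 30 mCmol/L/d dissolved
        util = co2_utilization(
            gas_volume_to_moles(6.0 * 1440.0),
            gas_volume_to_moles(4.0 * 1440.0),
            30.0,
        )
        assert util == pytest.approx(98.5, abs=0.05)

    def test_net_production_is_negative(self):
        assert co2_utilization(0.0, 10.0, 2.0) < 0


class TestDissolvedCO2:
    EQ = CO2Equilibrium(kh=0.026, pka1=6.31)

    def test_zero_pressure(self):
        assert dissolved_co2_effluent(6.5, 35.0, 0.0, 560.0, 1.0, self.EQ) == 0.0

    def test_linearity_in_pco2(self):
        one = dissolved_co2_effluent(6.5, 35.0, 0.25, 560.0, 1.0, self.EQ)
        two = dissolved_co2_effluent(6.5, 35.0, 0.5, 560.0, 1.0, self.EQ)
        assert two == pytest.approx(2.0 * one)

    def test_hand_arithmetic(self):
        # 0.026 * 0.5 * (1 + 10**(6.5 - 6.31)) * 0.56 * 1000 = 18.56
        got = dissolved_co2_effluent(6.5, 35.0, 0.5, 560.0, 1.0, self.EQ)
        assert got == pytest.approx(18.56, abs=0.01)

    def test_speciation_off_drops_bicarbonate(self):
        eq = CO2Equilibrium(kh=0.026, pka1=6.31, speciation=False)
        got = dissolved_co2_effluent(6.5, 35.0, 0.5, 560.0, 1.0, eq)
        assert got == pytest.approx(0.026 * 0.5 * 0.56 * 1000, rel=1e-9)

    def test_ph_validity_warning(self):
        with pytest.warns(UserWarning, match="pH"):
            dissolved_co2_effluent(2.0, 35.0, 0.5, 560.0, 1.0, self.EQ)

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValueError):
            dissolved_co2_effluent(6.5, 35.0, 1.5, 560.0, 1.0, self.EQ)


class TestH2Output:
    def test_zero_fraction(self):
        assert h2_output(10.0, 0.0, 1.0) == 0.0

    def test_arithmetic(self):
        # 10 NmL/min * 0.05 * 1440 / 22.414 = 32.1 mmol/L/d
        assert h2_output(10.0, 0.05, 1.0) == pytest.approx(32.12, abs=0.01)

    def test_unit_identity(self):
        assert h2_output(22.414, 1.0, 1.0) == pytest.approx(1440.0, abs=0.1)
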