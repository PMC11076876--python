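"""CSTR simulator: closed-form checks, stoichiometric closure, noise model,
determinism and scenario presets."""

import numpy as np
import pytest

from ceflux.simulate import (
    DEFAULT_REACTIONS,
    STUDY_FEED,
    ReactionSet,
    apply_measurement_noise,
    build_preset,
    default_sample_times,
    scenario_presets,
    simulate_reactor,
)
from ceflux.timeseries import PhaseDefinition, write_timeseries

PHASE = [PhaseDefinition("A", 0.0, 20.0, co2_load=0.0)]


@pytest.mark.parametrize("reaction", DEFAULT_REACTIONS, ids=lambda r: r.name)
def test_reactions_close_elements_exactly(registry, reaction):
    imbalance = registry.reaction_element_imbalance(reaction.stoichiometry)
    assert all(v == 0 for v in imbalance.values())


def test_reaction_set_rejects_unbalanced():
    from ceflux.simulate import Reaction

    with pytest.raises(ValueError, match="close"):
        ReactionSet([Reaction("bad", {"ethanol": -1, "acetate": 1})])


def test_washin_matches_closed_form():
    """With no reactions, each species follows C_f * (1 - exp(-t/tau))."""
    ts, _ = simulate_reactor(
        STUDY_FEED, PHASE, {}, feed_flow=522.0, init="zero",
        sample_times=np.linspace(0.0, 20.0, 21),
    )
    tau = 1.0 / 0.522  # V/Q in days
    for s in ts.samples:
        for name, cf_ in STUDY_FEED.composition.items():
            expected = cf_ * (1.0 - np.exp(-s.time / tau))
            assert s.broth[name] == pytest.approx(expected, abs=1e-4 * cf_)


def test_ce1_only_steady_state_algebra():
    """Constant CE1 drives acetate below feed level and butyrate to the
    algebraic CSTR steady state, at 1:1 mol stoichiometry."""
    rate = 5.0  # mmol/L/d
    ts, _ = simulate_reactor(
        STUDY_FEED, [PhaseDefinition("A", 0.0, 60.0)], {"CE1": rate},
        feed_flow=522.0, init="feed",
        sample_times=np.linspace(0.0, 60.0, 31),
    )
    q = 0.522
    last = ts.samples[-1].broth
    acetate_ss = (q * 50.0 - 1.0 * rate * 2.0) / q
    butyrate_ss = (q * 600.0 + 1.0 * rate * 4.0) / q
    assert last["acetate"] == pytest.approx(acetate_ss, rel=1e-4)
    assert last["n-butyrate"] == pytest.approx(butyrate_ss, rel=1e-4)
    assert last["acetate"] < 50.0  # drawn below feed level


def test_homoacetogenesis_consumes_dosed_co2():
    """EO supplies H2; HAC draws down CO2 so off-gas CO2 < dosed CO2."""
    phases = [PhaseDefinition("III", 0.0, 20.0, co2_load=6.0, n2_load=6.0)]
    ts, truth = simulate_reactor(
        STUDY_FEED, phases, {"EO": 20.0, "HAC": 9.0}, init="steady"
    )
    dosed_mmol_d = 6.0 * 1440.0 / 22.414
    s = ts.samples[-1]
    out_gas_co2 = s.gas_out_flow * s.headspace["CO2"] * 1440.0 / 22.414
    assert out_gas_co2 < dosed_mmol_d
    assert truth.intervals[-1]["gas_net_mmol_L_d"]["CO2"] == pytest.approx(-18.0)


def test_h2_overdraw_is_infeasible():
    with pytest.raises(ValueError, match="H2"):
        simulate_reactor(STUDY_FEED, PHASE, {"HAC": 5.0}, init="steady")


def test_negative_concentration_aborts_with_diagnostic():
    # CE1 consuming far more acetate than the feed supplies
    with pytest.raises(ValueError, match="acetate"):
        simulate_reactor(STUDY_FEED, PHASE, {"CE1": 100.0}, init="feed")


def test_underpressure_flagged_when_co2_demand_exceeds_supply():
    phases = [PhaseDefinition("A", 0.0, 20.0, co2_load=0.1, n2_load=1.0)]
    ts, truth = simulate_reactor(
        STUDY_FEED, phases, {"EO": 20.0, "HAC": 9.0}, init="steady"
    )
    # 18 mmol CO2/L/d demanded vs ~6.4 dosed
    assert truth.underpressure_times


def test_ground_truth_net_rates_are_stoich_times_rates(registry):
    ts, truth = build_preset("phaseIV", seed=3)
    reactions = ReactionSet(DEFAULT_REACTIONS, registry)
    for iv in truth.intervals[::7]:
        r = iv["reaction_rates_mmol_L_d"]
        for species, net in iv["net_rates_mCmol_L_d"].items():
            n_c = registry[species].carbon_number
            expected = n_c * sum(
                reac.coefficient(species) * r[reac.name] for reac in reactions
            )
            assert net == pytest.approx(expected, abs=1e-9)


class TestMeasurementNoise:
    def test_zero_cv_is_identity(self):
        ts, _ = build_preset("phaseI", seed=5)
        noised = apply_measurement_noise(ts, 0.0, seed=5)
        assert all(
            a.broth == b.broth for a, b in zip(ts.samples, noised.samples)
        )

    def test_same_seed_reproducible(self):
        ts, _ = build_preset("phaseI", seed=5)
        a = apply_measurement_noise(ts, 0.05, seed=42)
        b = apply_measurement_noise(ts, 0.05, seed=42)
        assert all(x.broth == y.broth for x, y in zip(a.samples, b.samples))
        c = apply_measurement_noise(ts, 0.05, seed=43)
        assert any(x.broth != y.broth for x, y in zip(a.samples, c.samples))

    def test_empirical_cv_matches(self):
        """1000 noisy replicates of one value show the configured scatter."""
        from ceflux.timeseries import ReactorTimeSeries, Sample

        ts = ReactorTimeSeries(
            "R", 1.0,
            [Sample(time=float(t), broth={"ethanol": 500.0}) for t in range(1000)],
        )
        noised = apply_measurement_noise(ts, 0.05, seed=0)
        vals = np.array([s.broth["ethanol"] for s in noised.samples])
        assert vals.std() / vals.mean() == pytest.approx(0.05, abs=0.005)


def test_fixed_seed_byte_identical_outputs(tmp_path):
    for run in ("a", "b"):
        ts, truth = build_preset("phaseII", seed=9, noise_cv=0.03)
        write_timeseries(ts, tmp_path / f"{run}.csv")
        truth.to_json(tmp_path / f"{run}.json")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()


def test_default_sampling_schedule_three_per_week():
    times = default_sample_times(21.0)
    assert times[0] == 0.0 and times[-1] < 21.0
    assert np.all(np.diff(times) >= 2.0) and np.all(np.diff(times) <= 3.0)


def test_unknown_preset_rejected():
    with pytest.raises(KeyError, match="unknown preset"):
        build_preset("phaseV")


def test_presets_document_their_ground_truth(preset_runs):
    """The nominal EEO fraction each preset advertises matches the exact
    per-interval truth at the end-of-run plateau."""
    presets = scenario_presets()
    for name, (ts, truth, _, _) in preset_runs.items():
        nominal = 100.0 * presets[name].nominal_eeo_fraction
        final = truth.intervals[-1]["eeo_pct"]
        assert final == pytest.approx(nominal, abs=1.0), name
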