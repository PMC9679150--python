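"""Core model: variant registry, stimulus, Euler integration, reset rule,
and the analytic subthreshold fixed point."""

import dataclasses
import math

import numpy as np
import pytest

from ca1pyr.model import (
    ModelParameters,
    NeuronState,
    NoSubthresholdEquilibrium,
    NumericalInstabilityError,
    SimulationConfig,
    StimulusProtocol,
    UnknownVariantError,
    applied_current,
    dump_variants,
    euler_step,
    load_variants,
    simulate,
    subthreshold_fixed_point,
    variant_parameters,
    variant_registry,
    write_trace_bundle,
)


@pytest.mark.parametrize(
    "name,expected",
    [
        ("Pyr_Strong", dict(C_m=115.0, a=0.0012, d=10.0, k_low=0.1, I_shift=0.0)),
        ("Pyr_Weak1", dict(C_m=300.0, a=0.001, d=5.0, k_low=0.5, I_shift=-45.0)),
        ("Pyr_Weak2", dict(C_m=300.0, a=0.00008, d=5.0, k_low=0.5, I_shift=-45.0)),
    ],
)
def test_variant_constants(name, expected):
    p = variant_parameters(name)
    for field, value in expected.items():
        assert getattr(p, field) == value
    # constants shared by all three variants
    assert (p.v_r, p.v_t, p.c, p.v_peak) == (-61.8, -57.0, -65.8, 22.6)
    assert (p.k_high, p.b) == (3.3, 3.0)


@pytest.mark.parametrize("alias", ["pyr_strong", "PYR_STRONG", "strongly adapting", "Strong"])
def test_variant_lookup_is_case_insensitive(alias):
    assert variant_parameters(alias).name == "Pyr_Strong"


def test_unknown_variant_lists_valid_names():
    with pytest.raises(UnknownVariantError, match="Pyr_Strong.*Pyr_Weak1.*Pyr_Weak2"):
        variant_parameters("Pyr_Bogus")


def test_registry_is_immutable_by_contract():
    reg = variant_registry()
    reg["Pyr_Strong"] = None
    assert variant_parameters("Pyr_Strong") is not None
    p = variant_parameters("Pyr_Strong")
    q = p.replace(d=11.0)
    assert q.d == 11.0 and variant_parameters("Pyr_Strong").d == 10.0
    with pytest.raises(dataclasses.FrozenInstanceError):
        p.d = 11.0


def test_parameter_invariants_are_enforced():
    p = variant_parameters("Pyr_Strong").to_dict()
    with pytest.raises(ValueError):
        ModelParameters(**{**p, "C_m": 0.0})
    with pytest.raises(ValueError):
        ModelParameters(**{**p, "k_low": 5.0})  # k_low > k_high
    with pytest.raises(ValueError):
        ModelParameters(**{**p, "v_t": -70.0})  # v_t < v_r


@pytest.mark.parametrize(
    "t,expected",
    [(500.0, 188.0), (0.0, 188.0), (999.98, 188.0), (1000.0, 0.0), (1200.0, 0.0)],
)
def test_applied_current_half_open_window(t, expected):
    proto = StimulusProtocol(amplitude=188.0, t_start=0.0, t_stop=1000.0,
                             t_total=2000.0)
    assert applied_current(proto, t) == expected


def test_applied_current_rejects_out_of_range_time():
    proto = StimulusProtocol(amplitude=-50.0, t_start=0.0, t_stop=1000.0,
                             t_total=2000.0)
    with pytest.raises(ValueError):
        applied_current(proto, -1.0)
    with pytest.raises(ValueError):
        applied_current(proto, 2000.1)


def test_protocol_window_validation():
    with pytest.raises(ValueError):
        StimulusProtocol(amplitude=0.0, t_start=500.0, t_stop=400.0, t_total=1000.0)
    with pytest.raises(ValueError):
        StimulusProtocol(amplitude=0.0, t_start=0.0, t_stop=1500.0, t_total=1000.0)


class TestEulerStep:
    def test_rest_state_is_a_fixed_point(self):
        p = variant_parameters("Pyr_Strong")
        out = euler_step(NeuronState(V=-61.8, u=0.0), p, I_ext=0.0, dt=0.02)
        assert out.state == NeuronState(-61.8, 0.0)
        assert not out.spiked

    def test_k_low_at_threshold_exactly(self):
        # at V == v_t the low gain applies, so the quadratic term vanishes
        p = variant_parameters("Pyr_Strong")
        out = euler_step(NeuronState(V=p.v_t, u=0.0), p, I_ext=100.0, dt=0.02)
        expected_v = p.v_t + 0.02 * 100.0 / p.C_m  # k*(V-v_r)*(V-v_t) == 0
        assert out.state.V == pytest.approx(expected_v, abs=1e-12)

    def test_k_high_just_above_threshold(self):
        p = variant_parameters("Pyr_Strong")
        V = p.v_t + 1e-6
        out = euler_step(NeuronState(V=V, u=0.0), p, I_ext=0.0, dt=0.02)
        expected = V + 0.02 * (p.k_high * (V - p.v_r) * (V - p.v_t)) / p.C_m
        assert out.state.V == pytest.approx(expected, rel=1e-12)

    def test_reset_rule(self, variant_params):
        p = variant_params
        # a state guaranteed to overshoot v_peak in one step
        out = euler_step(NeuronState(V=22.0, u=0.0), p, I_ext=5000.0, dt=0.5)
        assert out.spiked
        assert out.v_raw >= p.v_peak
        assert out.state.V == p.c
        u_no_spike = 0.0 + 0.5 * (p.a * (p.b * (22.0 - p.v_r) - 0.0))
        assert out.state.u == pytest.approx(u_no_spike + p.d, rel=1e-12)

    def test_rejects_bad_dt_and_nonfinite(self):
        p = variant_parameters("Pyr_Strong")
        with pytest.raises(ValueError):
            euler_step(NeuronState(-65.0, 0.0), p, 0.0, dt=0.0)
        with pytest.raises(NumericalInstabilityError):
            euler_step(NeuronState(1e200, 0.0), p, 0.0, dt=0.02)


def test_simulate_matches_repeated_euler_steps():
    """The vectorized trace must be the literal iteration of euler_step
    with the windowed stimulus current."""
    p = variant_parameters("Pyr_Strong")
    proto = StimulusProtocol(amplitude=150.0, t_start=10.0, t_stop=40.0,
                             t_total=60.0)
    cfg = SimulationConfig()
    res = simulate(p, proto, cfg)

    state = NeuronState(cfg.v_init, cfg.u_init)
    vm = [cfg.v_init]
    spikes = []
    n = round(proto.t_total / cfg.dt)
    for i in range(n):
        out = euler_step(state, p, applied_current(proto, i * cfg.dt), cfg.dt)
        vm.append(out.v_raw)
        if out.spiked:
            spikes.append(res.times[i + 1])
        state = out.state
    assert np.array_equal(res.vm, np.array(vm))
    assert np.array_equal(res.spike_times, np.array(spikes))
    assert spikes, "protocol chosen to spike at least once"


def test_resting_simulation_stays_at_rest():
    p = variant_parameters("Pyr_Strong")
    res = simulate(p, StimulusProtocol(0.0, 0.0, 1000.0, 1000.0),
                   SimulationConfig(v_init=-61.8, u_init=0.0))
    assert res.n_spikes == 0
    assert np.max(np.abs(res.vm + 61.8)) < 0.01


def test_simulation_is_deterministic_and_grid_aligned(run_sim):
    a = simulate(variant_parameters("Pyr_Strong"),
                 StimulusProtocol(250.0, 0.0, 1000.0, 1000.0))
    b = simulate(variant_parameters("Pyr_Strong"),
                 StimulusProtocol(250.0, 0.0, 1000.0, 1000.0))
    assert np.array_equal(a.vm, b.vm) and np.array_equal(a.spike_times, b.spike_times)

    res = run_sim("Pyr_Strong", 250.0)
    assert len(res.times) == len(res.vm) == 50001
    assert np.allclose(np.diff(res.times), 0.02)
    # every spike time lies on the sampling grid, strictly increasing, in range
    assert np.all(np.diff(res.spike_times) > 0)
    assert res.spike_times[0] >= 0 and res.spike_times[-1] <= 1000.0
    idx = np.round(res.spike_times / 0.02).astype(int)
    assert np.array_equal(res.times[idx], res.spike_times)
    # the crossing sample stores the raw overshoot, the next one the reset
    assert np.all(res.vm[idx] >= variant_parameters("Pyr_Strong").v_peak)
    assert np.all(res.vm[idx + 1] < 0)


def test_time_grid_must_match_dt():
    p = variant_parameters("Pyr_Strong")
    with pytest.raises(ValueError, match="integer multiple"):
        simulate(p, StimulusProtocol(0.0, 0.0, 0.05, 1000.03),
                 SimulationConfig(dt=0.02))


def test_rebound_spiking_pattern(run_sim):
    """Release from hyperpolarization elicits spikes in the excitable
    variants (after stimulus offset only), and none in Pyr_Weak2."""
    strong = run_sim("Pyr_Strong", -50.0, t_stop=1000.0, t_total=2000.0)
    assert strong.n_spikes >= 1
    assert np.all(strong.spike_times > 1000.0)
    weak1 = run_sim("Pyr_Weak1", -1000.0, t_stop=1000.0, t_total=2000.0)
    assert weak1.n_spikes == 1 and weak1.spike_times[0] > 1000.0
    weak2 = run_sim("Pyr_Weak2", -1000.0, t_stop=1000.0, t_total=2000.0)
    assert weak2.n_spikes == 0


class TestSubthresholdFixedPoint:
    def test_strong_rest_is_exact(self):
        assert subthreshold_fixed_point(variant_parameters("Pyr_Strong"), 0.0) == -61.8

    def test_weak_rest_matches_quadratic_formula(self):
        # stable root of 0.5 x^2 - 5.4 x - 45 = 0, x = V - v_r
        # x^2 - 10.8 x - 90 = 0 after dividing by k_low = 0.5
        x = (10.8 - math.sqrt(10.8**2 + 4 * 90.0)) / 2.0
        expected = -61.8 + x
        for name in ("Pyr_Weak1", "Pyr_Weak2"):
            assert subthreshold_fixed_point(variant_parameters(name), 0.0) == \
                pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-67.316, abs=5e-4)

    def test_no_equilibrium_above_saddle_node(self):
        with pytest.raises(NoSubthresholdEquilibrium):
            subthreshold_fixed_point(variant_parameters("Pyr_Strong"), 1000.0)

    @pytest.mark.parametrize(
        "name,I,t_settle,tol",
        [
            ("Pyr_Strong", 0.0, 5000.0, 0.1),
            ("Pyr_Strong", -44.8, 5000.0, 0.1),
            ("Pyr_Weak1", -20.0, 5000.0, 0.1),
            # tau_u = 1/a = 12.5 s: Pyr_Weak2 needs a much longer settle
            ("Pyr_Weak2", -20.0, 30000.0, 0.5),
        ],
    )
    def test_simulated_steady_state_agrees(self, name, I, t_settle, tol):
        p = variant_parameters(name)
        res = simulate(p, StimulusProtocol(I, 0.0, t_settle, t_settle))
        assert res.n_spikes == 0
        assert res.vm[-1] == pytest.approx(subthreshold_fixed_point(p, I), abs=tol)


def test_dt_refinement_changes_frequencies_below_5_percent(run_sim):
    from ca1pyr.features import spike_frequencies

    coarse = run_sim("Pyr_Strong", 250.0)
    fine = run_sim("Pyr_Strong", 250.0, dt=0.01)
    for c, f in zip(spike_frequencies(coarse.spike_times),
                    spike_frequencies(fine.spike_times)):
        assert abs(c - f) / f < 0.05


@pytest.mark.parametrize("ext", ["yaml", "json"])
def test_variant_config_roundtrip(tmp_path, ext):
    path = tmp_path / f"variants.{ext}"
    dump_variants(path)
    loaded = load_variants(path)
    assert set(loaded) == {"Pyr_Strong", "Pyr_Weak1", "Pyr_Weak2"}
    for name, p in loaded.items():
        assert p == variant_parameters(name)


def test_load_variants_rejects_missing_parameters(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('{"X": {"v_r": -61.8}}')
    with pytest.raises(ValueError, match="missing parameters"):
        load_variants(path)


def test_trace_bundle_export(tmp_path, run_sim):
    res = run_sim("Pyr_Strong", 188.0)
    csv_path, json_path = write_trace_bundle(res, tmp_path / "trace")
    arr = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    assert arr.shape == (len(res.times), 2)
    assert np.allclose(arr[:, 0], res.times, atol=1e-6)
    assert np.allclose(arr[:, 1], res.vm, atol=1e-6)
    import json

    side = json.loads(open(json_path).read())
    assert side["stim_start"] == 0.0 and side["stim_end"] == 1000.0
    assert side["variant"] == "Pyr_Strong"
    assert side["spike_times_ms"] == [float(t) for t in res.spike_times]
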