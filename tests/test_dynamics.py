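import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fasworm.connectome import Connectome, build_conductances, synthetic_connectome
from fasworm.dynamics import (
    ModelParams,
    NetworkState,
    euler_step,
    membrane_currents,
    resting_state,
    sigmoid_activation,
    simulate,
    synaptic_equilibrium,
)
from fasworm.injury import InjuryVector


def _single_neuron():
    return Connectome(["A"], np.zeros((1, 1)), np.zeros((1, 1)),
                      np.array(["excitatory"], dtype=object))


def _pair(ns_ab=1.0, polarity=("excitatory", "excitatory")):
    Ns = np.array([[0.0, ns_ab], [0.0, 0.0]])   # Ns[A, B]: synapse from B onto A
    return Connectome(["A", "B"], np.zeros((2, 2)), Ns, np.array(polarity, dtype=object))


# ---------------------------------------------------------------------------
# elementary functions


def test_sigmoid_midpoint_limits_and_closed_form():
    assert sigmoid_activation(-20.0, 0.125, -20.0) == pytest.approx(0.5)
    assert sigmoid_activation(1e6, 0.125, 0.0) == pytest.approx(1.0)
    assert sigmoid_activation(-1e6, 0.125, 0.0) == pytest.approx(0.0)
    # (v - v_th) = 8 mV at beta = 0.125 -> 1/(1 + e^-1)
    assert sigmoid_activation(8.0, 0.125, 0.0) == pytest.approx(1.0 / (1.0 + np.exp(-1.0)))


def test_synaptic_equilibrium_values_and_euler_limit():
    assert synaptic_equilibrium(0.0, 1.0, 5.0) == 0.0
    assert synaptic_equilibrium(1.0, 1.0, 5.0) == pytest.approx(1.0 / 6.0)
    # Euler-integrated s at clamped phi converges to the equilibrium value
    phi, ar, ad, dt = 0.7, 1.0, 5.0, 1e-4
    s = 0.0
    for _ in range(200_000):
        s += dt * (ar * phi * (1 - s) - ad * s)
    assert s == pytest.approx(synaptic_equilibrium(phi, ar, ad), rel=1e-6)


def test_gap_current_vanishes_at_equal_voltages():
    c = synthetic_connectome(6, density=0.6, seed=2)
    cond = build_conductances(c, 100.0)
    params = ModelParams(V_th=-35.0)
    erev = c.reversal_potentials(params.E_exc, params.E_inh)
    st_ = NetworkState(np.full(6, -12.0), np.random.default_rng(0).random(6))
    I_gap, _ = membrane_currents(st_, cond, params, erev)
    assert np.allclose(I_gap, 0.0, atol=1e-9)


def test_single_excitatory_synapse_current_value():
    c = _pair()
    cond = build_conductances(c, 100.0)
    params = ModelParams(V_th=-35.0)
    erev = c.reversal_potentials(params.E_exc, params.E_inh)
    st_ = NetworkState(np.array([-35.0, -35.0]), np.array([0.0, 1.0]))
    _, I_syn = membrane_currents(st_, cond, params, erev)
    # Gs = 100 pS, s_B = 1, V_A = -35, E_B = 0 -> 100 * (-35) = -3500
    assert I_syn[0] == pytest.approx(-3500.0)
    assert I_syn[1] == pytest.approx(0.0)


def test_membrane_currents_match_double_loop_oracle():
    rng = np.random.default_rng(7)
    c = synthetic_connectome(6, density=0.7, inhibitory_fraction=0.5, seed=4)
    cond = build_conductances(c, 100.0)
    params = ModelParams(V_th=-35.0)
    erev = c.reversal_potentials(params.E_exc, params.E_inh)
    V = rng.normal(-30, 10, 6)
    s = rng.random(6)
    I_gap, I_syn = membrane_currents(NetworkState(V, s), cond, params, erev)
    for i in range(6):
        g = sum(cond.Gg[i, j] * (V[i] - V[j]) for j in range(6))
        sy = sum(cond.Gs[i, j] * s[j] * (V[i] - erev[j]) for j in range(6))
        assert I_gap[i] == pytest.approx(g, rel=1e-12)
        assert I_syn[i] == pytest.approx(sy, rel=1e-12)


# ---------------------------------------------------------------------------
# Euler integration


def test_unconnected_neuron_rests_at_leak_potential():
    c = _single_neuron()
    cond = build_conductances(c, 100.0)
    params = ModelParams(V_th=-35.0)
    erev = c.reversal_potentials(params.E_exc, params.E_inh)
    state = NetworkState(np.array([-35.0]), np.array([0.0]))
    for _ in range(100):
        state = euler_step(state, cond, params, erev)
    assert state.V[0] == pytest.approx(-35.0)


def test_constant_input_fixed_point_is_Ecell_plus_I_over_Gc():
    c = _single_neuron()
    params = ModelParams(V_th=-35.0)
    traj = simulate(c, params, I_ext={"A": 200.0}, T=3.0, stride=100)
    # analytic fixed point: E_cell + I/Gc = -35 + 20 = -15 mV
    assert traj.V[-1, 0] == pytest.approx(-15.0, abs=1e-6)


def test_euler_matches_analytic_exponential_to_first_order():
    # single uncoupled neuron from V0: V(t) = E + (V0-E) exp(-Gc t / C)
    c = _single_neuron()
    errs = {}
    for dt in (2e-4, 1e-4):
        params = ModelParams(V_th=-35.0, dt=dt)
        init = NetworkState(np.array([0.0]), np.array([0.0]))
        traj = simulate(c, params, T=0.5, stride=1, initial=init)
        exact = -35.0 + 35.0 * np.exp(-10.0 * traj.times)
        errs[dt] = np.abs(traj.V[:, 0] - exact).max()
    assert errs[1e-4] < 0.05   # O(dt) small absolute error
    ratio = errs[2e-4] / errs[1e-4]
    assert 1.5 < ratio < 2.5   # first-order convergence


def test_halving_dt_changes_voltages_at_first_order(oscillator_baseline):
    _, c, params, I_ext, rest, *_ = oscillator_baseline
    from dataclasses import replace

    t1 = simulate(c, params, I_ext=I_ext, T=1.0, stride=100, initial=rest)
    t2 = simulate(c, replace(params, dt=params.dt / 2), I_ext=I_ext, T=1.0, stride=200,
                  initial=rest)
    diff = np.abs(t1.V - t2.V).max()
    assert 0 < diff < 1.0   # O(dt) difference on a ~10 mV signal


def test_injury_mu_zero_is_bitwise_identical_to_healthy(oscillator_baseline):
    _, c, params, I_ext, rest, *_ = oscillator_baseline
    iv = InjuryVector(np.array([0, 0, 0.6, 0.8, 0.0]), c.neuron_names, ["SENL", "SENR"], mu=0.0)
    a = simulate(c, params, I_ext=I_ext, T=2.0, stride=100, initial=rest)
    b = simulate(c, params, injury=iv, I_ext=I_ext, T=2.0, stride=100, initial=rest)
    assert np.array_equal(a.V, b.V)


def test_extreme_swelling_isolates_neuron_at_leak_rate(oscillator_baseline):
    # a heavily swollen neuron decouples: V -> E_cell exponentially at rate Gc/C
    _, c, params, I_ext, rest, *_ = oscillator_baseline
    m = np.zeros(5)
    m[2] = 1.0   # OSC1 fully swollen
    iv = InjuryVector(m, c.neuron_names, [], mu=1e9)
    init = rest.copy()
    init.V[2] = 20.0
    traj = simulate(c, params, injury=iv, I_ext=I_ext, T=0.5, stride=10, initial=init)
    v = traj.V[:, c.index("OSC1")]
    exact = -35.0 + (20.0 + 35.0) * np.exp(-10.0 * traj.times)
    assert np.abs(v - exact).max() < 0.01 * 55.0   # within 1% of the excursion
    # fitted decay rate within 1% of Gc/C = 10 / s
    mask = (v - -35.0) > 1.0
    rate = -np.polyfit(traj.times[mask], np.log(v[mask] + 35.0), 1)[0]
    assert rate == pytest.approx(10.0, rel=0.01)


def test_common_potential_is_invariant_with_zero_input():
    # with E_exc = E_inh = E_cell and no input, V = E_cell is exactly invariant
    c = synthetic_connectome(5, density=0.6, inhibitory_fraction=0.5, seed=8)
    params = ModelParams(E_exc=-35.0, E_inh=-35.0, V_th=-35.0)
    init = NetworkState(np.full(5, -35.0), np.zeros(5))
    traj = simulate(c, params, T=1.0, stride=100, initial=init)
    assert np.allclose(traj.V, -35.0, atol=1e-9)


def test_synaptic_activity_stays_in_unit_interval(oscillator_baseline):
    _, c, params, I_ext, rest, *_ = oscillator_baseline
    traj, final = simulate(c, params, I_ext=I_ext, T=5.0, stride=50, initial=rest,
                           return_final=True)
    assert np.all(final.s >= 0.0) and np.all(final.s <= 1.0)


def test_nonfinite_state_is_reported_with_neuron():
    c = _pair()
    cond = build_conductances(c, 100.0)
    params = ModelParams(V_th=-35.0)
    erev = c.reversal_potentials(params.E_exc, params.E_inh)
    bad = NetworkState(np.array([np.nan, -35.0]), np.array([0.0, 0.0]))
    with pytest.raises(Exception, match="neuron index 0"):
        euler_step(bad, cond, params, erev)


# ---------------------------------------------------------------------------
# resting state


def test_resting_state_unconnected_equals_leak_potential():
    c = Connectome(["A", "B"], np.zeros((2, 2)), np.zeros((2, 2)),
                   np.array(["excitatory", "excitatory"], dtype=object))
    state, vth = resting_state(c, ModelParams())
    assert np.allclose(state.V, -35.0)
    assert np.allclose(vth, -35.0)


def test_resting_state_is_a_fixed_point_of_the_dynamics():
    from dataclasses import replace

    c = synthetic_connectome(8, density=0.4, inhibitory_fraction=0.3, seed=11)
    params = ModelParams()
    state, vth = resting_state(c, params)
    params = replace(params, V_th=vth)
    cond = build_conductances(c, params.g)
    erev = c.reversal_potentials(params.E_exc, params.E_inh)
    nxt = euler_step(state, cond, params, erev)
    assert np.abs(nxt.V - state.V).max() < 1e-9
    assert np.abs(nxt.s - state.s).max() < 1e-9


def test_excitatory_synapse_raises_postsynaptic_equilibrium():
    lone = Connectome(["A", "B"], np.zeros((2, 2)), np.zeros((2, 2)),
                      np.array(["excitatory", "excitatory"], dtype=object))
    coupled = _pair(ns_ab=5.0)   # B excites A
    v_lone, _ = resting_state(lone, ModelParams())
    v_coup, _ = resting_state(coupled, ModelParams())
    assert v_coup.V[0] > v_lone.V[0]   # pulled toward E_exc = 0 mV


def test_given_thresholds_converge_by_alternation():
    c = synthetic_connectome(6, density=0.5, seed=13)
    params = ModelParams(V_th=-30.0)
    state, vth = resting_state(c, params)
    assert np.allclose(vth, -30.0)
    from fasworm.dynamics import sigmoid_activation as sig

    s_expected = synaptic_equilibrium(sig(state.V, params.beta, vth), params.a_r, params.a_d)
    assert np.allclose(state.s, s_expected, atol=1e-8)


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    mu=st.floats(0.0, 50.0),
    m0=st.floats(0.0, 1.0),
)
def test_injury_factor_weakly_decreases_coupling(mu, m0):
    m = np.array([m0, np.sqrt(max(1 - m0**2, 0.0))])
    iv = InjuryVector(m / np.linalg.norm(m), ["A", "B"], [])
    s1 = iv.scale(mu)
    s2 = iv.scale(mu + 1.0)
    assert np.all(1.0 / s2 <= 1.0 / s1 + 1e-15)
    assert np.all(s1 >= 1.0)
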