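"""Cell dynamics: closed-form relaxation, range contracts, dense oracle."""

import numpy as np
import pytest

import semground as sg
from semground.areas import Area
from semground.connectivity import KernelParams
from semground.dynamics import (DynamicsParams, NonConvergenceError,
                                StimulusFrame, output_of, run,
                                run_until_baseline, zero_state)

from oracles import dense_reference_run


def quiet_dyn(**kw):
    base = dict(noise_amplitude=0.0)
    base.update(kw)
    return DynamicsParams(**base)


def test_zero_input_zero_noise_is_a_fixed_point(toy_network):
    state = zero_state(toy_network)
    run(toy_network, state, None, 20, quiet_dyn(), np.random.default_rng(0))
    assert np.all(state.V_e == 0) and np.all(state.O == 0)
    assert np.all(state.G == 0)


def test_single_cell_matches_leaky_integrator_closed_form(toy_network):
    """Constant drive I: V follows k_input*I*(1-(1-1/tau)^t) exactly."""
    dyn = quiet_dyn(k_global=0.0)
    # silence recurrent/inhibitory coupling by driving a cell with no inputs
    net = toy_network
    state = zero_state(net)
    drive = 0.2    # below output threshold: the cell never fires
    frame = StimulusFrame(driven={Area.AT: np.array([7])}, drive=drive)
    idx = int(Area.AT) * net.cells_per_area + 7
    lam = 1.0 - 1.0 / dyn.tau_e
    for t in range(1, 30):
        run(net, state, frame, 1, dyn, np.random.default_rng(0))
        expected = dyn.k_input * drive * (1.0 - lam**t)
        assert state.V_e[idx] == pytest.approx(expected, rel=1e-12)


def test_outputs_bounded_and_G_nonnegative(toy_network):
    rng = np.random.default_rng(3)
    dyn = DynamicsParams(noise_amplitude=0.5)
    state = zero_state(toy_network)
    for _ in range(10):
        cells = rng.choice(toy_network.cells_per_area, 5, replace=False)
        frame = StimulusFrame(driven={Area.A1: cells}, drive=rng.uniform(0, 6))
        run(toy_network, state, frame, 10, dyn, rng)
        assert np.all(state.O >= 0) and np.all(state.O <= 1)
        assert np.all(state.G >= -1e-12)


def test_activity_decays_to_zero_without_noise(toy_network):
    rng = np.random.default_rng(4)
    state = zero_state(toy_network)
    frame = StimulusFrame(driven={Area.A1: np.arange(10)}, drive=4.0)
    dyn = quiet_dyn()
    run(toy_network, state, frame, 16, dyn, rng)
    run(toy_network, state, None, 300, dyn, rng)
    assert state.O.sum() == pytest.approx(0.0, abs=1e-6)


def test_output_function_shape():
    dyn = DynamicsParams()
    lo = dyn.output_threshold
    assert output_of(lo - 1.0, 0.0, dyn) == 0.0
    assert output_of(lo + 2.0, 0.0, dyn) == 1.0
    # linear mid-range, verified against the scalar formula on a grid
    for v in np.linspace(lo, lo + 1, 11):
        for om in (0.0, 0.1, 0.3):
            expect = min(max(v - lo - dyn.alpha_adapt * om, 0.0), 1.0)
            assert output_of(v, om, dyn) == pytest.approx(expect)
    # monotonicity: nondecreasing in V, nonincreasing in adaptation
    vs = output_of(np.linspace(-1, 3, 50), 0.2, dyn)
    assert np.all(np.diff(vs) >= 0)
    oms = output_of(1.0, np.linspace(0, 1, 50), dyn)
    assert np.all(np.diff(oms) <= 0)


def test_adaptation_habituates_sustained_drive(toy_network):
    rng = np.random.default_rng(5)
    state = zero_state(toy_network)
    frame = StimulusFrame(driven={Area.V1: np.arange(6)}, drive=4.0)
    dyn = quiet_dyn()
    idx = int(Area.V1) * toy_network.cells_per_area
    out5 = out50 = None
    for t in range(1, 51):
        run(toy_network, state, frame, 1, dyn, rng)
        if t == 5:
            out5 = state.O[idx:idx + 6].mean()
        if t == 50:
            out50 = state.O[idx:idx + 6].mean()
    assert out50 <= out5


def test_sparse_step_equals_dense_reference(toy_network):
    """100 random steps, plasticity off: fused kernel vs dense loops."""
    dyn = DynamicsParams(noise_amplitude=0.3)
    rng_pkg = np.random.default_rng(77)
    rng_ref = np.random.default_rng(77)
    state_pkg = zero_state(toy_network)
    state_ref = zero_state(toy_network)
    cells = np.random.default_rng(1).choice(25, 6, replace=False)
    frame = StimulusFrame(driven={Area.A1: cells, Area.V1: cells}, drive=3.0)
    stim_vec = frame.to_vector(toy_network)
    run(toy_network, state_pkg, frame, 100, dyn, rng_pkg)
    noise = rng_ref.uniform(-dyn.noise_amplitude, dyn.noise_amplitude,
                            size=(100, toy_network.n_excitatory))
    dense_reference_run(toy_network, state_ref, stim_vec, noise, dyn)
    for name in ("V_e", "V_i", "omega", "O", "G"):
        np.testing.assert_allclose(getattr(state_pkg, name),
                                   getattr(state_ref, name),
                                   rtol=1e-10, atol=1e-12, err_msg=name)


def test_sparse_learning_run_equals_dense_reference(toy_network):
    """30 random steps with plasticity: weights match the scalar-rule oracle."""
    import copy
    net = copy.deepcopy(toy_network)
    dyn = DynamicsParams(noise_amplitude=0.3)
    plast = sg.PlasticityParams(theta_pre=0.05, theta_plus=0.3,
                                theta_minus=0.15, delta_w=0.05, w_max=1.2)
    ref_net = copy.deepcopy(net)
    frame = StimulusFrame(driven={Area.A1: np.arange(8)}, drive=4.0)
    stim_vec = frame.to_vector(net)
    state = zero_state(net)
    run(net, state, frame, 30, dyn, np.random.default_rng(9), plasticity=plast)
    ref_state = zero_state(ref_net)
    noise = np.random.default_rng(9).uniform(-0.3, 0.3,
                                             size=(30, net.n_excitatory))
    W_ref = dense_reference_run(ref_net, ref_state, stim_vec, noise, dyn,
                                plast=plast)
    rows, cols = net.weights.nonzero()
    np.testing.assert_allclose(np.asarray(net.weights[rows, cols]).ravel(),
                               W_ref[rows, cols], rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(state.V_e, ref_state.V_e, rtol=1e-10,
                               atol=1e-12)


def test_baseline_relaxation_contract(toy_network):
    dyn = DynamicsParams(noise_amplitude=0.05)
    state = zero_state(toy_network)
    # already below threshold -> zero steps
    _, steps = run_until_baseline(toy_network, state, dyn,
                                  np.random.default_rng(0))
    assert steps == 0
    # drive the watch areas hard, then relaxation takes > 0 steps
    rng = np.random.default_rng(1)
    frame = StimulusFrame(driven={Area.PF_i: np.arange(20),
                                  Area.PB: np.arange(20)}, drive=5.0)
    run(toy_network, state, frame, 16, dyn, rng)
    assert state.G[int(Area.PF_i)] > dyn.baseline_threshold
    _, steps = run_until_baseline(toy_network, state, dyn, rng)
    assert steps > 0
    assert state.G[int(Area.PF_i)] < dyn.baseline_threshold
    assert state.G[int(Area.PB)] < dyn.baseline_threshold


def test_default_baseline_criterion_value():
    assert DynamicsParams().baseline_threshold == 0.65


def test_nonconvergence_raises(toy_network):
    dyn = DynamicsParams(noise_amplitude=0.05)
    state = zero_state(toy_network)
    state.G[int(Area.PF_i)] = 100.0
    state.G[int(Area.PB)] = 100.0
    # tau_global never lets G fall that fast in 3 steps
    with pytest.raises(NonConvergenceError):
        run_until_baseline(toy_network, state, dyn, np.random.default_rng(0),
                           max_steps=3)


def test_shape_mismatch_rejected(toy_network):
    state = zero_state(toy_network)
    state.V_e = state.V_e[:-1]
    with pytest.raises(ValueError):
        run(toy_network, state, None, 1, DynamicsParams(),
            np.random.default_rng(0))
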