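"""Circuit dynamics: operating points, WTA, dopamine effects, oracle checks."""
import dataclasses

import numpy as np
import pytest
from scipy import optimize

from gonogo import BGNetwork, NetworkParams, PlasticWeights, sigmoid_activation
from gonogo.network import NO_RESPONSE
from gonogo.params import load_params, save_params


def test_sigmoid_activation_shape():
    assert sigmoid_activation(1.0, slope=4, center=1.0) == pytest.approx(0.5)
    assert sigmoid_activation(1e3) == pytest.approx(1.0)
    assert sigmoid_activation(-1e3) == pytest.approx(0.0)
    x = np.linspace(-5, 5, 101)
    y = sigmoid_activation(x)
    assert np.all(np.diff(y) > 0) and np.all((y > 0) & (y < 1))


def test_resting_operating_points(net2, naive_weights):
    """Zero stimulus: cortex/thalamus/striatum silent, GPe at half
    activation, GPi near its upper saturation."""
    rest = net2.resting_state(naive_weights)
    assert np.all(rest.cortex < 0.05) and np.all(rest.thalamus < 0.05)
    assert np.all(rest.go < 0.15) and np.all(rest.nogo < 0.15)
    assert np.all((rest.gpe > 0.4) & (rest.gpe < 0.6))
    assert np.all(rest.gpi > 0.8)


def test_naive_trial_operating_points(net2, naive_weights, stimulus):
    """A naive suprathreshold trial: one motor channel wins above 0.9 and
    the winner-channel Go and NoGo settle near 0.5 before feedback."""
    noise = np.array([0.05, 0.0])
    state, _, converged = net2.run_to_steady_state(stimulus, naive_weights,
                                                  D=1.0, noise_c=noise)
    assert converged
    w = net2.detect_response(state.cortex)
    assert w == 0
    assert state.cortex[w] > 0.9 and state.cortex[1] < 0.1
    assert state.go[w] == pytest.approx(0.5, abs=0.05)
    assert state.nogo[w] == pytest.approx(0.5, abs=0.05)


def test_zero_dt_step_is_identity(net2, naive_weights, stimulus):
    u = np.linspace(-0.5, 1.5, 13)
    u2 = net2.step(u, stimulus, naive_weights, D=1.0,
                   noise_c=np.zeros(2), dt=0.0)
    assert np.array_equal(u, u2)


def test_slow_and_fast_integration_agree(net2, naive_weights, stimulus):
    """The pure-numpy Euler stepping reproduces the jitted kernel."""
    p = dataclasses.replace(net2.params, ss_tol=0.0, max_steps=60)
    fast = BGNetwork(p, 2)
    noise = np.array([0.1, -0.05])
    _, u_fast, _ = fast.run_to_steady_state(stimulus, naive_weights, 1.3,
                                            noise)
    u = fast.zero_state()
    for _ in range(60):
        u = fast.step(u, stimulus, naive_weights, 1.3, noise)
    assert np.allclose(u, u_fast, atol=1e-10)


def test_steady_state_is_algebraic_fixed_point(net2, naive_weights,
                                               trained_weights, stimulus):
    """The integrated steady state solves the algebraic system u = net(y(u)),
    and an independent root-finder started nearby converges to it."""
    a = net2._slope_vec()
    for w, D in ((naive_weights, 1.0), (trained_weights, 1.0),
                 (naive_weights, 2.0), (trained_weights, 0.0)):
        noise = np.array([0.05, 0.0])
        _, u_star, conv = net2.run_to_steady_state(stimulus, w, D, noise)
        assert conv

        def residual(u):
            y = 1.0 / (1.0 + np.exp(-a * (u - net2.params.center)))
            return net2.net_inputs(y, stimulus, w, D, noise) - u

        # the Euler stopping rule leaves ~1e-2 slack in membrane units
        assert np.max(np.abs(residual(u_star))) < 0.02
        rng = np.random.default_rng(0)
        sol = optimize.root(residual, u_star + rng.normal(0, 0.02, u_star.size))
        assert sol.success
        assert np.allclose(sol.x, u_star, atol=0.02)


def test_winner_takes_all_uniqueness(net2, naive_weights, stimulus):
    """At most one motor neuron exceeds 0.9 at steady state, for many
    independent noise draws."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        noise = rng.normal(0, net2.params.noise_sd, 2)
        state, _, _ = net2.run_to_steady_state(stimulus, naive_weights, 1.0,
                                               noise)
        assert np.sum(state.cortex > 0.9) <= 1


def test_dopamine_monotonicity(net2, naive_weights, trained_weights,
                               stimulus):
    """Winner Go activity is non-decreasing and every NoGo activity is
    non-increasing in the dopaminergic input."""
    noise = np.array([0.05, 0.0])
    for w in (naive_weights, trained_weights):
        _, u0, _ = net2.run_to_steady_state(stimulus, w, 1.0, noise)
        gos, nogos = [], []
        for D in np.linspace(0.5, 2.5, 9):
            state, _, _ = net2.run_to_steady_state(stimulus, w, D, noise,
                                                   u0=u0)
            gos.append(state.go[0])
            nogos.append(state.nogo.copy())
        assert np.all(np.diff(gos) > -1e-6)
        nogos = np.array(nogos)
        assert np.all(np.diff(nogos, axis=0) < 1e-6)
        assert np.all(nogos[-1] < nogos[0])   # strictly lower at high D


def test_activities_bounded_for_extreme_inputs(net2, naive_weights):
    s = np.array([5.0, -3.0])
    for D in (-2.0, 0.0, 5.0):
        state, _, _ = net2.run_to_steady_state(s, naive_weights, D,
                                               np.array([2.0, -2.0]))
        for arr in (state.cortex, state.go, state.nogo, state.gpe,
                    state.gpi, state.thalamus):
            assert np.all((arr >= 0.0) & (arr <= 1.0))


@pytest.mark.parametrize("cortex, expected", [
    ([0.95, 0.02], 0),
    ([0.02, 0.95], 1),
    ([0.95, 0.95], NO_RESPONSE),   # multiple responses
    ([0.50, 0.30], NO_RESPONSE),   # absence of a response
    ([0.95, 0.30], NO_RESPONSE),   # loser not close to zero
])
def test_detect_response_criterion(net2, cortex, expected):
    assert net2.detect_response(np.array(cortex)) == expected


def test_nonconvergence_is_flagged_not_fatal(net2, naive_weights, stimulus):
    p = dataclasses.replace(net2.params, max_steps=5)
    short = BGNetwork(p, 2)
    state, _, converged = short.run_to_steady_state(stimulus, naive_weights,
                                                    1.0, np.zeros(2))
    assert not converged
    assert state.cortex.shape == (2,)


def test_dimension_mismatch_raises(net2, naive_weights):
    with pytest.raises(ValueError):
        net2.run_to_steady_state(np.ones(3), naive_weights, 1.0, np.zeros(2))
    with pytest.raises(ValueError):
        net2.run_to_steady_state(np.ones(2), naive_weights, 1.0, np.zeros(3))


def test_params_roundtrip(tmp_path, net2):
    path = tmp_path / "params.yaml"
    save_params(path, net2.params)
    loaded = load_params(path)
    assert loaded == net2.params
    (tmp_path / "bad.yaml").write_text("no_such_param: 1\n")
    with pytest.raises(ValueError):
        load_params(tmp_path / "bad.yaml")


def test_four_channel_topology(net4):
    w = PlasticWeights.naive(4, 4, net4.params)
    rest = net4.resting_state(w)
    assert rest.cortex.shape == (4,)
    assert np.all((rest.gpe > 0.4) & (rest.gpe < 0.6))
    assert np.all(rest.gpi > 0.8)
    s = np.array([1.0, 0.3, 0.1, 0.1])
    noise = np.array([0.05, 0.0, -0.02, 0.01])
    state, _, _ = net4.run_to_steady_state(s, w, 1.0, noise)
    assert np.sum(state.cortex > 0.9) <= 1
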