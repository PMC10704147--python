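"""Tests for the surrogate gradient, loss, BPTT and the training loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adjoint_oracle import oracle_gradients
from leakysnn.analysis import make_network, evaluate_accuracy
from leakysnn.event_io import bundle_dataset
from leakysnn.synthetic import SyntheticSpec, generate
from leakysnn.training import (
    Adamax,
    SurrogateConfig,
    TrainConfig,
    backward_pass,
    fast_sigmoid,
    fast_sigmoid_grad,
    forward_pass,
    init_decays,
    init_weights,
    max_over_time_loss,
    train,
)
from leakysnn.dynamics import NeuronModelConfig, run_network


# ---------------------------------------------------------------------------
# surrogate


def test_fast_sigmoid_worked_values():
    assert fast_sigmoid(0.0) == 0.0
    assert fast_sigmoid_grad(0.0) == 1.0
    assert fast_sigmoid(0.01, 100.0) == pytest.approx(0.005)
    assert fast_sigmoid(1e9, 100.0) == pytest.approx(1 / 100.0, rel=1e-6)
    assert fast_sigmoid_grad(1e9, 100.0) == pytest.approx(0.0, abs=1e-12)


@given(st.floats(-1e6, 1e6, allow_nan=False), st.floats(0.1, 1e4))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_surrogate_derivative_positive_and_bounded(x, steep):
    g = fast_sigmoid_grad(x, steep)
    assert 0.0 < g <= 1.0


# ---------------------------------------------------------------------------
# loss


def test_loss_two_class_worked_example():
    """Maxima [2, 0] with true class 0: -log(e^2 / (e^2 + e^0))."""
    u = np.array([[2.0, 0.0], [1.0, -1.0]])  # max over time = [2, 0]
    expected = -math.log(math.exp(2) / (math.exp(2) + 1))
    assert max_over_time_loss(u, 0) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.12693, abs=1e-5)


@pytest.mark.parametrize("k", [2, 5, 20])
def test_loss_uniform_maxima_is_log_k(k):
    u = np.ones((4, k)) * 0.7
    for label in (0, k - 1):
        assert max_over_time_loss(u, label) == pytest.approx(math.log(k), rel=1e-12)


def test_loss_vanishes_as_true_class_max_grows():
    u = np.zeros((1, 3))
    u[0, 1] = 50.0
    assert max_over_time_loss(u, 1) == pytest.approx(0.0, abs=1e-20)


@given(st.floats(-100, 100))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_loss_shift_invariance(c):
    rng = np.random.default_rng(0)
    u = rng.normal(size=(6, 3, 4))
    labels = np.array([0, 3, 1])
    assert max_over_time_loss(u + c, labels) == pytest.approx(
        max_over_time_loss(u, labels), rel=1e-9, abs=1e-12
    )


def test_loss_rejects_bad_label():
    with pytest.raises(ValueError):
        max_over_time_loss(np.zeros((3, 4)), 4)


def test_batch_loss_is_mean_of_per_sample_losses():
    rng = np.random.default_rng(3)
    u = rng.normal(size=(5, 4, 3))
    labels = np.array([0, 1, 2, 0])
    per_sample = [max_over_time_loss(u[:, i], labels[i]) for i in range(4)]
    assert max_over_time_loss(u, labels) == pytest.approx(np.mean(per_sample), rel=1e-12)


# ---------------------------------------------------------------------------
# backward pass vs independent oracle


@pytest.mark.parametrize("kind, tau_mem, tau_syn", [
    ("if", math.inf, 0.0),
    ("lif", 140.0, 0.0),
    ("cuba_lif", 140.0, 28.0),
])
@pytest.mark.parametrize("recurrent", [False, True])
@pytest.mark.parametrize("reset_grad", [False, True])
def test_backward_matches_adjoint_oracle(kind, tau_mem, tau_syn, recurrent, reset_grad):
    """Vectorized BPTT equals the scalar chain-rule oracle (rel tol 1e-6)."""
    rng = np.random.default_rng(17)
    net = make_network(kind, 6, 8, 3, recurrent, tau_mem_ms=tau_mem, tau_syn_ms=tau_syn, seed=17)
    net.w_in *= 3.0  # drive the layer into a spiking regime
    x = (rng.random((9, 3, 6)) < 0.35).astype(float)
    labels = rng.integers(0, 3, 3)
    cache = forward_pass(x, net)
    assert cache.s.sum() > 0  # the fixture must actually spike
    g = backward_pass(cache, net, labels, SurrogateConfig(100.0),
                      grad_through_reset=reset_grad, want_decay_grads=True)
    a, b = net.effective_hidden_decays()
    o = oracle_gradients(x, labels, net.w_in, net.effective_v_rec(), net.w_out,
                         a, b, net.readout_cfg.alpha, net.readout_cfg.beta,
                         steepness=100.0, grad_through_reset=reset_grad)
    assert g.loss == pytest.approx(o["loss"], rel=1e-12)
    for name in ("w_in", "w_out", "v_rec", "alpha", "beta"):
        mine = getattr(g, name)
        if mine is None:
            assert name == "v_rec" and not recurrent
            continue
        scale = max(np.abs(o[name]).max(), 1e-12)
        np.testing.assert_allclose(mine, o[name], atol=1e-6 * scale)


def test_zero_network_zero_input_gives_zero_gradients():
    net = make_network("lif", 4, 5, 2, True, tau_mem_ms=140.0, tau_syn_ms=0.0, seed=0)
    net.w_in[:] = net.w_out[:] = net.v_rec[:] = 0.0
    x = np.zeros((6, 2, 4))
    g = backward_pass(forward_pass(x, net), net, np.array([0, 1]))
    # readout potentials are identically zero: uniform softmax, but no
    # pathway carries gradient back to any weight
    assert not g.w_in.any() and not g.v_rec.any() and not g.w_out.any()


def test_feedforward_network_has_no_recurrent_gradient():
    net = make_network("lif", 4, 5, 2, False, tau_mem_ms=140.0, tau_syn_ms=0.0, seed=1)
    g = backward_pass(forward_pass(np.ones((5, 2, 4)), net), net, np.array([0, 1]))
    assert g.v_rec is None


def test_forward_pass_matches_run_network(rng):
    net = make_network("cuba_lif", 5, 7, 3, True, tau_mem_ms=140.0, tau_syn_ms=14.0, seed=2)
    net.w_in *= 2.0
    x = (rng.random((12, 4, 5)) < 0.3).astype(float)
    cache = forward_pass(x, net)
    trace = run_network(x, net, record_hidden_state=True)
    np.testing.assert_array_equal(cache.s, trace.hidden_spikes)
    np.testing.assert_allclose(cache.u2, trace.readout_u, atol=1e-12)


# ---------------------------------------------------------------------------
# initialization


def test_init_weights_deterministic_and_scaled():
    w1a, va, w2a = init_weights(100, 50, 10, True, seed=5)
    w1b, vb, w2b = init_weights(100, 50, 10, True, seed=5)
    np.testing.assert_array_equal(w1a, w1b)
    np.testing.assert_array_equal(va, vb)
    w1c, _, _ = init_weights(100, 50, 10, True, seed=6)
    assert not np.array_equal(w1a, w1c)
    big, _, _ = init_weights(100, 1000, 10, False, seed=7)
    assert big.std() == pytest.approx(0.1, rel=0.05)  # 1/sqrt(fan-in 100)


def test_init_decays_homogeneous_and_random():
    cfg = NeuronModelConfig.cuba_lif(tau_syn_ms=14.0, tau_mem_ms=420.0)
    d = init_decays("homogeneous_init", cfg, 16, seed=0)
    np.testing.assert_allclose(d.beta, 0.967, atol=1e-3)
    np.testing.assert_allclose(d.alpha, cfg.alpha, atol=1e-12)
    r1 = init_decays("random_init", cfg, 64, seed=9)
    r2 = init_decays("random_init", cfg, 64, seed=9)
    np.testing.assert_array_equal(r1.raw_beta, r2.raw_beta)
    assert np.all((r1.alpha > 0.05) & (r1.alpha < 0.995))
    assert np.all((r1.beta > 0.05) & (r1.beta < 0.995))


def test_decay_parameterization_round_trip():
    cfg = NeuronModelConfig.lif(tau_mem_ms=140.0)
    d = init_decays("homogeneous_init", cfg, 4, seed=0)
    np.testing.assert_allclose(d.beta, cfg.beta, atol=1e-12)
    assert not d.train_alpha  # alpha = 0 is structural for LIF


def test_init_decays_requires_heterogeneity_mode():
    with pytest.raises(ValueError):
        init_decays("none", NeuronModelConfig.lif(140.0), 4, seed=0)


# ---------------------------------------------------------------------------
# optimizer and training loop


def _tiny_task(structure="spatial", n_classes=2, n_steps=25, seed=5):
    spec = SyntheticSpec(
        structure=structure, n_classes=n_classes, n_steps=n_steps,
        n_train_per_class=25, n_test_per_class=15, seed=seed,
    )
    tr, te = generate(spec)
    return bundle_dataset(tr), bundle_dataset(te)


def test_zero_learning_rate_changes_nothing():
    trb, teb = _tiny_task()
    net = make_network("lif", trb.n_channels, 10, 2, False, tau_mem_ms=140.0, tau_syn_ms=0.0, seed=3)
    w0 = net.w_in.copy()
    cfg = TrainConfig(learning_rate=0.0, batch_size=16, epochs=3, n_class=2, seed=0)
    res = train(trb.x, trb.labels, teb.x, teb.labels, net, cfg)
    np.testing.assert_array_equal(net.w_in, w0)
    assert res.history["test_accuracy"].nunique() == 1


def test_training_is_seed_reproducible():
    trb, teb = _tiny_task()
    hist = []
    for _ in range(2):
        net = make_network("lif", trb.n_channels, 10, 2, False, tau_mem_ms=140.0, tau_syn_ms=0.0, seed=3)
        cfg = TrainConfig(learning_rate=5e-3, batch_size=16, epochs=3, n_class=2, seed=7)
        hist.append(train(trb.x, trb.labels, teb.x, teb.labels, net, cfg).history)
    np.testing.assert_array_equal(hist[0]["train_loss"], hist[1]["train_loss"])
    np.testing.assert_array_equal(hist[0]["test_accuracy"], hist[1]["test_accuracy"])


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_separable_two_class_task_learned(seed):
    """A rate-coded 2-class task is learned to >= 95% within 30 epochs."""
    trb, teb = _tiny_task()
    net = make_network("lif", trb.n_channels, 32, 2, False, tau_mem_ms=140.0, tau_syn_ms=0.0, seed=seed)
    cfg = TrainConfig(learning_rate=5e-3, batch_size=16, epochs=30, n_class=2, seed=seed)
    train(trb.x, trb.labels, teb.x, teb.labels, net, cfg)
    assert evaluate_accuracy(net, teb) >= 0.95


def test_heterogeneous_training_keeps_decays_in_unit_interval():
    trb, teb = _tiny_task()
    net = make_network("cuba_lif", trb.n_channels, 12, 2, False,
                       tau_mem_ms=140.0, tau_syn_ms=14.0, seed=4)
    cfg = TrainConfig(learning_rate=5e-3, batch_size=16, epochs=5, n_class=2,
                      heterogeneity="homogeneous_init", seed=4)
    res = train(trb.x, trb.labels, teb.x, teb.labels, net, cfg)
    a, b = res.learned_decays["alpha"], res.learned_decays["beta"]
    assert np.all((a > 0) & (a < 1)) and np.all((b > 0) & (b < 1))
    # decays moved away from their common initialization: heterogeneity emerged
    assert a.std() > 0 or b.std() > 0
    assert np.all(res.learned_decays["tau_mem_ms"] > 0)


def test_adamax_moves_parameter_against_gradient():
    p = {"w": np.array([1.0])}
    opt = Adamax(p, lr=0.1)
    opt.step({"w": np.array([2.0])})
    assert p["w"][0] < 1.0
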