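"""Surrogate-gradient BPTT training of spiking networks.

The forward pass keeps the hard spiking non-linearity
``S = Theta(U - theta)``; only the backward pass replaces the step
function's derivative (zero almost everywhere) with the derivative of the
fast sigmoid ``sigma(x) = x / (1 + steep*|x|)``, namely
``1 / (1 + steep*|x|)^2`` evaluated at ``x = U - theta``.  The loss is the
max-over-time cross entropy: each readout neuron contributes the maximum of
its membrane potential over the sample, and those per-class maxima are
softmaxed.  Optimization uses Adamax.

The whole reverse pass is written as an explicit adjoint recursion over the
unrolled dynamics (reverse-mode autodiff by hand); there is no autodiff
framework underneath.  By default the reset gate ``(1 - S[t-1])`` is treated
as a constant in the backward pass — gradients flow through spikes only via
the synaptic drives they produce — which is the usual stabilization; set
``grad_through_reset=True`` to differentiate through the gate as well.

Heterogeneous (trainable) time constants are handled by parameterizing each
per-neuron decay as ``sigmoid(raw)`` so alpha and beta stay strictly inside
(0, 1) at every optimization step without clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import (
    ModelKind,
    NetworkSpec,
    NeuronModelConfig,
    SimulationTrace,
    decay_from_tau,
    run_network,
    predict,
)

__all__ = [
    "SurrogateConfig",
    "TrainConfig",
    "DecayParameterization",
    "TrainResult",
    "Gradients",
    "ForwardCache",
    "fast_sigmoid",
    "fast_sigmoid_grad",
    "max_over_time_loss",
    "forward_pass",
    "backward_pass",
    "init_weights",
    "init_decays",
    "train",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Fast-sigmoid steepness; larger values approach the true step."""

    steepness: float = 100.0

    def __post_init__(self):
        if not self.steepness > 0:
            raise ValueError("steepness must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 5e-3
    batch_size: int = 128
    epochs: int = 50
    n_class: int = 2
    heterogeneity: str = "none"  # none | homogeneous_init | random_init
    seed: int = 0
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    adamax_betas: tuple[float, float] = (0.9, 0.999)
    adamax_eps: float = 1e-8
    grad_through_reset: bool = False

    def __post_init__(self):
        if not self.learning_rate >= 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.heterogeneity not in ("none", "homogeneous_init", "random_init"):
            raise ValueError(f"unknown heterogeneity mode {self.heterogeneity!r}")


def fast_sigmoid(x: np.ndarray | float, steepness: float = 100.0) -> np.ndarray | float:
    """Fast sigmoid ``x / (1 + steepness * |x|)``, the surrogate spike."""
    x = np.asarray(x, dtype=float)
    out = x / (1.0 + steepness * np.abs(x))
    return out.item() if out.ndim == 0 else out


def fast_sigmoid_grad(x: np.ndarray | float, steepness: float = 100.0) -> np.ndarray | float:
    """Derivative ``1 / (1 + steepness*|x|)^2`` used in the backward pass."""
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + steepness * np.abs(x)) ** 2
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Loss


def _per_class_maxima(readout_u: np.ndarray) -> np.ndarray:
    """(n_steps, ..., n_class) -> per-class max over time (..., n_class)."""
    return np.asarray(readout_u, dtype=float).max(axis=0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def max_over_time_loss(
    readout_u: np.ndarray,
    label: int | np.ndarray,
    n_class: Optional[int] = None,
) -> float:
    """Cross entropy on the per-class max-over-time readout potentials.

    ``readout_u`` is (n_steps, n_class) for a single sample or
    (n_steps, batch, n_class); the batch loss is the mean over samples.
    """
    u = np.asarray(readout_u, dtype=float)
    single = u.ndim == 2
    if single:
        u = u[:, None, :]
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    k = u.shape[-1]
    if n_class is not None and n_class != k:
        raise ValueError(f"readout has {k} classes, expected {n_class}")
    if np.any(labels < 0) or np.any(labels >= k):
        raise ValueError(f"label out of range [0, {k})")
    m = _per_class_maxima(u)  # (batch, k)
    logp = m - m.max(axis=-1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
    return float(-logp[np.arange(len(labels)), labels].mean())


# ---------------------------------------------------------------------------
# Forward pass with cached intermediates


@dataclass
class ForwardCache:
    """Everything the adjoint recursion needs, recorded during forward.

    All arrays are (n_steps, batch, width); ``u1_pre`` is the membrane
    before the reset gate is applied.
    """

    x: np.ndarray
    i1: np.ndarray
    u1_pre: np.ndarray
    u1: np.ndarray
    s: np.ndarray
    i2: np.ndarray
    u2: np.ndarray

    @property
    def trace(self) -> SimulationTrace:
        return SimulationTrace(self.s, self.u2, hidden_u=self.u1, hidden_i=self.i1)


def forward_pass(x: np.ndarray, net: NetworkSpec) -> ForwardCache:
    """Batched simulation recording all intermediates for BPTT.

    ``x`` is (n_steps, batch, n_in) binary.  Produces the same trajectories
    as :func:`leakysnn.dynamics.run_network` (asserted by the test suite).
    """
    x = np.asarray(x, dtype=float)
    n_steps, batch, _ = x.shape
    h, o = net.n_hidden, net.n_out
    a, b = net.effective_hidden_decays()
    a2, b2 = net.readout_cfg.alpha, net.readout_cfg.beta
    v = net.effective_v_rec()
    th = net.hidden_cfg.threshold

    i1 = np.zeros((n_steps, batch, h))
    u1_pre = np.zeros((n_steps, batch, h))
    u1 = np.zeros((n_steps, batch, h))
    s = np.zeros((n_steps, batch, h))
    i2 = np.zeros((n_steps, batch, o))
    u2 = np.zeros((n_steps, batch, o))

    i1_prev = np.zeros((batch, h))
    u1_prev = np.zeros((batch, h))
    s_prev = np.zeros((batch, h))
    i2_prev = np.zeros((batch, o))
    u2_prev = np.zeros((batch, o))
    for t in range(n_steps):
        drive = x[t] @ net.w_in.T
        if v is not None:
            drive = drive + s_prev @ v.T
        i1[t] = a * i1_prev + drive
        u1_pre[t] = b * u1_prev + i1[t]
        u1[t] = u1_pre[t] * (1.0 - s_prev)
        s[t] = (u1[t] >= th).astype(float)
        i2[t] = a2 * i2_prev + s_prev @ net.w_out.T
        u2[t] = b2 * u2_prev + i2[t]
        i1_prev, u1_prev, s_prev = i1[t], u1[t], s[t]
        i2_prev, u2_prev = i2[t], u2[t]
    return ForwardCache(x, i1, u1_pre, u1, s, i2, u2)


# ---------------------------------------------------------------------------
# Backward pass


@dataclass
class Gradients:
    w_in: np.ndarray
    w_out: np.ndarray
    v_rec: Optional[np.ndarray]
    alpha: Optional[np.ndarray] = None  # per-neuron hidden synaptic decay
    beta: Optional[np.ndarray] = None  # per-neuron hidden membrane decay
    loss: float = 0.0

    def check_finite(self):
        for name in ("w_in", "w_out", "v_rec", "alpha", "beta"):
            g = getattr(self, name)
            if g is not None and not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in {name}")


def backward_pass(
    cache: ForwardCache,
    net: NetworkSpec,
    labels: np.ndarray,
    surrogate: SurrogateConfig = SurrogateConfig(),
    grad_through_reset: bool = False,
    want_decay_grads: bool = False,
) -> Gradients:
    """Adjoint recursion through the unrolled dynamics.

    Wherever the spike derivative dS/dU appears it is replaced by the
    fast-sigmoid derivative at (U - theta).  Gradients are means over the
    batch (matching the 1/N_batch loss prefactor).  When
    ``want_decay_grads`` is set, per-neuron gradients for the hidden decay
    strengths alpha and beta are accumulated as well.
    """
    x, s = cache.x, cache.s
    n_steps, batch, _ = x.shape
    h, o = net.n_hidden, net.n_out
    a, b = net.effective_hidden_decays()
    a2, b2 = net.readout_cfg.alpha, net.readout_cfg.beta
    v = net.effective_v_rec()
    th = net.hidden_cfg.threshold
    labels = np.asarray(labels, dtype=int)

    # loss and its gradient routed to the argmax time step of each class
    m = cache.u2.max(axis=0)  # (batch, o)
    t_star = cache.u2.argmax(axis=0)  # (batch, o), first maximum on ties
    p = _softmax(m)
    loss = float(-(np.log(p[np.arange(batch), labels] + 1e-300)).mean())
    dm = p.copy()
    dm[np.arange(batch), labels] -= 1.0
    dm /= batch

    g_surr = fast_sigmoid_grad(cache.u1 - th, surrogate.steepness)

    gw1 = np.zeros_like(net.w_in)
    gw2 = np.zeros_like(net.w_out)
    gv = np.zeros_like(v) if v is not None else None
    ga = np.zeros(h) if want_decay_grads else None
    gb = np.zeros(h) if want_decay_grads else None

    du2_next = np.zeros((batch, o))
    di2_next = np.zeros((batch, o))
    du1_next = np.zeros((batch, h))
    di1_next = np.zeros((batch, h))
    r_next = np.ones((batch, h))  # reset gate at t+1 (unused at t = T-1)
    sample_idx = np.arange(batch)[:, None]
    class_idx = np.arange(o)[None, :]
    for t in range(n_steps - 1, -1, -1):
        s_prev = s[t - 1] if t > 0 else np.zeros((batch, h))
        r_t = 1.0 - s_prev

        du2 = b2 * du2_next
        hit = t_star == t
        du2 = du2 + np.where(hit, dm, 0.0)
        di2 = du2 + a2 * di2_next

        # hidden spikes at t feed step t+1: recurrent drive, readout drive,
        # and (optionally) the reset gate
        ds = di2_next @ net.w_out
        if v is not None:
            ds = ds + di1_next @ v
        if grad_through_reset and t + 1 < n_steps:
            ds = ds - cache.u1_pre[t + 1] * du1_next
        du1 = g_surr[t] * ds + b * (du1_next * r_next)
        di1 = du1 * r_t + a * di1_next

        gw1 += di1.T @ x[t]
        gw2 += di2.T @ s_prev
        if gv is not None:
            gv += di1.T @ s_prev
        if want_decay_grads:
            i1_prev = cache.i1[t - 1] if t > 0 else np.zeros((batch, h))
            u1_prev = cache.u1[t - 1] if t > 0 else np.zeros((batch, h))
            ga += (di1 * i1_prev).sum(axis=0)
            gb += (du1 * r_t * u1_prev).sum(axis=0)

        du2_next, di2_next = du2, di2
        du1_next, di1_next = du1, di1
        r_next = r_t

    if net.zero_self_connections and gv is not None:
        np.fill_diagonal(gv, 0.0)
    grads = Gradients(gw1, gw2, gv, ga, gb, loss)
    grads.check_finite()
    return grads


# ---------------------------------------------------------------------------
# Initialization


def init_weights(
    n_in: int, n_hidden: int, n_out: int, recurrent: bool, seed: int
) -> tuple[np.ndarray, Optional[np.ndarray], np.ndarray]:
    """Zero-mean Gaussian weights with std 1/sqrt(fan-in) per matrix."""
    rng = np.random.default_rng(seed)
    w_in = rng.normal(0.0, 1.0 / math.sqrt(n_in), size=(n_hidden, n_in))
    v_rec = (
        rng.normal(0.0, 1.0 / math.sqrt(n_hidden), size=(n_hidden, n_hidden))
        if recurrent
        else None
    )
    w_out = rng.normal(0.0, 1.0 / math.sqrt(n_hidden), size=(n_out, n_hidden))
    return w_in, v_rec, w_out


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class DecayParameterization:
    """Trainable per-neuron decays via logistic squashing.

    ``decay = sigmoid(raw)`` keeps every trained decay strictly inside
    (0, 1).  A decay whose initial value sits on the boundary (alpha = 0 for
    IF/LIF, beta = 1 for IF) is structural, not trainable: its mask entry is
    False and it is held fixed.
    """

    raw_alpha: np.ndarray
    raw_beta: np.ndarray
    train_alpha: bool
    train_beta: bool

    @property
    def alpha(self) -> np.ndarray:
        return _sigmoid(self.raw_alpha) if self.train_alpha else np.zeros_like(self.raw_alpha)

    @property
    def beta(self) -> np.ndarray:
        return _sigmoid(self.raw_beta) if self.train_beta else np.ones_like(self.raw_beta)


def init_decays(
    mode: str,
    cfg: NeuronModelConfig,
    n_hidden: int,
    seed: int,
    random_low: float = 0.05,
    random_high: float = 0.995,
) -> DecayParameterization:
    """Initial decay parameterization for heterogeneous training.

    ``homogeneous_init`` starts every neuron at the config's
    (alpha, beta); ``random_init`` draws per-neuron decays uniformly on
    (random_low, random_high).  Raw values are the inverse logistic of the
    decays.  Boundary decays (0 or 1) stay fixed, so an IF layer trains
    neither and a LIF layer trains beta only.
    """
    if mode not in ("homogeneous_init", "random_init"):
        raise ValueError(f"init_decays requires a heterogeneity mode, got {mode!r}")
    a0, b0 = cfg.alpha, cfg.beta
    train_alpha = 0.0 < a0 < 1.0
    train_beta = 0.0 < b0 < 1.0
    rng = np.random.default_rng(seed)
    if mode == "homogeneous_init":
        alpha = np.full(n_hidden, a0 if train_alpha else 0.5)
        beta = np.full(n_hidden, b0 if train_beta else 0.5)
    else:
        alpha = rng.uniform(random_low, random_high, n_hidden)
        beta = rng.uniform(random_low, random_high, n_hidden)
        if not train_alpha:
            alpha = np.full(n_hidden, 0.5)
        if not train_beta:
            beta = np.full(n_hidden, 0.5)
    return DecayParameterization(_logit(alpha), _logit(beta), train_alpha, train_beta)


# ---------------------------------------------------------------------------
# Optimizer


class Adamax:
    """Adamax: Adam with an infinity-norm second moment."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(p) for k, p in params.items()}
        self.u = {k: np.zeros_like(p) for k, p in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bias = 1.0 - self.b1**self.t
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.u[k] = np.maximum(self.b2 * self.u[k], np.abs(g))
            self.params[k] -= (self.lr / bias) * self.m[k] / (self.u[k] + self.eps)


# ---------------------------------------------------------------------------
# Training loop


@dataclass
class TrainResult:
    net: NetworkSpec
    history: "pd.DataFrame"  # columns: epoch, train_loss, test_accuracy
    seed: int
    learned_decays: Optional[dict[str, np.ndarray]] = None


def _evaluate(net: NetworkSpec, x: np.ndarray, labels: np.ndarray, chunk: int = 256) -> float:
    n = x.shape[1]
    correct = 0
    for lo in range(0, n, chunk):
        trace = run_network(x[:, lo : lo + chunk], net)
        correct += int((predict(trace) == labels[lo : lo + chunk]).sum())
    return correct / n


def train(
    train_x: np.ndarray,
    train_labels: np.ndarray,
    test_x: np.ndarray,
    test_labels: np.ndarray,
    net: NetworkSpec,
    cfg: TrainConfig,
) -> TrainResult:
    """Run epochs of forward/backward/Adamax updates on a fixed network.

    ``train_x``/``test_x`` are (n_steps, n_samples, n_in) binary rasters.
    The network's weight matrices are updated in place; with heterogeneity
    enabled, the hidden layer's per-neuron decays are learned jointly and
    the result records the final (alpha, beta) vectors and the implied time
    constants.  Deterministic given ``cfg.seed`` on one device.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    n_train = train_x.shape[1]
    heterogeneous = cfg.heterogeneity != "none"
    decays = None
    if heterogeneous:
        decays = init_decays(cfg.heterogeneity, net.hidden_cfg, net.n_hidden, seed=cfg.seed + 1)
        net.hidden_alpha = decays.alpha
        net.hidden_beta = decays.beta

    params: dict[str, np.ndarray] = {"w_in": net.w_in, "w_out": net.w_out}
    if net.recurrent:
        params["v_rec"] = net.v_rec
    if heterogeneous:
        if decays.train_alpha:
            params["raw_alpha"] = decays.raw_alpha
        if decays.train_beta:
            params["raw_beta"] = decays.raw_beta
    opt = Adamax(params, cfg.learning_rate, cfg.adamax_betas, cfg.adamax_eps)

    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        losses = []
        for lo in range(0, n_train, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb, yb = train_x[:, idx], train_labels[idx]
            cache = forward_pass(xb, net)
            grads = backward_pass(
                cache,
                net,
                yb,
                cfg.surrogate,
                grad_through_reset=cfg.grad_through_reset,
                want_decay_grads=heterogeneous,
            )
            if not math.isfinite(grads.loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                )
            gdict = {"w_in": grads.w_in, "w_out": grads.w_out}
            if net.recurrent:
                gdict["v_rec"] = grads.v_rec
            if heterogeneous:
                # chain rule through decay = sigmoid(raw)
                if decays.train_alpha:
                    aa = decays.alpha
                    gdict["raw_alpha"] = grads.alpha * aa * (1.0 - aa)
                if decays.train_beta:
                    bb = decays.beta
                    gdict["raw_beta"] = grads.beta * bb * (1.0 - bb)
            opt.step(gdict)
            if heterogeneous:
                net.hidden_alpha = decays.alpha
                net.hidden_beta = decays.beta
            losses.append(grads.loss)
        acc = _evaluate(net, test_x, test_labels)
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "test_accuracy": acc}
        )

    history = pd.DataFrame(rows)
    learned = None
    if heterogeneous:
        dt = net.hidden_cfg.dt_ms
        with np.errstate(divide="ignore"):
            learned = {
                "alpha": decays.alpha.copy(),
                "beta": decays.beta.copy(),
                "tau_syn_ms": np.where(
                    decays.alpha > 0, -dt / np.log(np.clip(decays.alpha, 1e-300, 1)), 0.0
                ),
                "tau_mem_ms": -dt / np.log(np.clip(decays.beta, 1e-300, 1 - 1e-12)),
            }
    return TrainResult(net=net, history=history, seed=cfg.seed, learned_decays=learned)
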