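"""Discrete-time simulation of IF, LIF and CUBA-LIF spiking layers.

The three neuron models share one pair of update equations, applied per
neuron ``i`` in layer ``l`` at step ``t``::

    I_i[t] = alpha * I_i[t-1] + sum_j W_ij S_j^(l-1)[t-1] + sum_j V_ij S_j^(l)[t-1]
    U_i[t] = (beta * U_i[t-1] + I_i[t]) * (1 - S_i[t-1])
    S_i[t] = 1  iff  U_i[t] >= theta

with decay strengths ``alpha = exp(-dt/tau_syn)`` and
``beta = exp(-dt/tau_mem)``.  IF is the special case ``alpha = 0, beta = 1``
(no leaks), LIF is ``alpha = 0`` (instantaneous synapse, leaky membrane) and
CUBA-LIF keeps both exponential compartments.  A spike at ``t-1`` zeroes the
whole membrane expression at ``t``, including the incoming current — a hard
reset to the resting potential ``U_rest = 0``.

The readout layer uses the same current/membrane updates with an infinite
threshold: it never spikes and is never reset, so its membrane integrates
the hidden activity and classification reads the per-class maximum over
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "ModelKind",
    "TimeGrid",
    "NeuronModelConfig",
    "NetworkSpec",
    "LayerState",
    "SimulationTrace",
    "decay_from_tau",
    "layer_step",
    "readout_step",
    "run_network",
    "predict",
]

#: Firing threshold theta shared by all spiking layers.
THRESHOLD = 1.0
#: Resting potential; membranes reset to this value after a spike.
U_REST = 0.0


class ModelKind(str, Enum):
    IF = "if"
    LIF = "lif"
    CUBA_LIF = "cuba_lif"


def decay_from_tau(tau_ms: float, dt_ms: float) -> float:
    """Per-step decay strength ``exp(-dt/tau)`` for a time constant.

    ``tau_ms = 0`` encodes an infinite leak (decay 0, the state is fully
    forgotten each step); ``tau_ms = inf`` encodes no leak (decay 1).  These
    sentinels make IF and LIF exact sub-cases of CUBA-LIF rather than
    numerical limits.

    Parameters
    ----------
    tau_ms : time constant in milliseconds (0, positive, or ``math.inf``).
    dt_ms : simulation step in milliseconds, strictly positive.
    """
    if not dt_ms > 0:
        raise ValueError(f"dt_ms must be positive, got {dt_ms}")
    if tau_ms < 0 or math.isnan(tau_ms):
        raise ValueError(f"tau_ms must be >= 0 or inf, got {tau_ms}")
    if tau_ms == 0:
        return 0.0
    if math.isinf(tau_ms):
        return 1.0
    return math.exp(-dt_ms / tau_ms)


def tau_from_decay(decay: float, dt_ms: float) -> float:
    """Inverse of :func:`decay_from_tau`: ``tau = -dt / ln(decay)``."""
    if decay <= 0:
        return 0.0
    if decay >= 1:
        return math.inf
    return -dt_ms / math.log(decay)


@dataclass(frozen=True)
class TimeGrid:
    """Simulation clock: step width and number of steps per sample."""

    dt_ms: float = 14.0
    n_steps: int = 100

    def __post_init__(self):
        if not self.dt_ms > 0:
            raise ValueError("dt_ms must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.n_steps * self.dt_ms / 1000.0


@dataclass(frozen=True)
class NeuronModelConfig:
    """Neuron model kind with its time constants and derived decays.

    ``alpha``/``beta`` are stored explicitly so that trained (heterogeneous)
    decays can be represented without a corresponding tau; for scalar
    configs they always satisfy ``alpha = exp(-dt/tau_syn)`` and
    ``beta = exp(-dt/tau_mem)``.
    """

    kind: ModelKind
    tau_syn_ms: float
    tau_mem_ms: float
    dt_ms: float = 14.0
    threshold: float = THRESHOLD
    u_rest: float = U_REST
    r_in: float = 1.0

    @property
    def alpha(self) -> float:
        return decay_from_tau(self.tau_syn_ms, self.dt_ms)

    @property
    def beta(self) -> float:
        return decay_from_tau(self.tau_mem_ms, self.dt_ms)

    def __post_init__(self):
        kind = ModelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        a, b = self.alpha, self.beta
        if kind is ModelKind.IF:
            if a != 0.0 or b != 1.0:
                raise ValueError(
                    "IF requires tau_syn=0 (alpha=0) and tau_mem=inf (beta=1); "
                    f"got alpha={a}, beta={b}"
                )
        elif kind is ModelKind.LIF:
            if a != 0.0:
                raise ValueError(f"LIF requires tau_syn=0 (alpha=0); got alpha={a}")
            if not b < 1.0:
                raise ValueError(f"LIF requires beta < 1 (finite tau_mem); got beta={b}")
        if not (0.0 <= a < 1.0):
            raise ValueError(f"alpha must lie in [0, 1), got {a}")
        if not (0.0 < b <= 1.0):
            raise ValueError(f"beta must lie in (0, 1], got {b}")

    @classmethod
    def if_model(cls, dt_ms: float = 14.0) -> "NeuronModelConfig":
        return cls(ModelKind.IF, tau_syn_ms=0.0, tau_mem_ms=math.inf, dt_ms=dt_ms)

    @classmethod
    def lif(cls, tau_mem_ms: float, dt_ms: float = 14.0) -> "NeuronModelConfig":
        return cls(ModelKind.LIF, tau_syn_ms=0.0, tau_mem_ms=tau_mem_ms, dt_ms=dt_ms)

    @classmethod
    def cuba_lif(
        cls, tau_syn_ms: float, tau_mem_ms: float, dt_ms: float = 14.0
    ) -> "NeuronModelConfig":
        return cls(ModelKind.CUBA_LIF, tau_syn_ms=tau_syn_ms, tau_mem_ms=tau_mem_ms, dt_ms=dt_ms)


@dataclass
class NetworkSpec:
    """Three-layer topology: input -> hidden (spiking) -> readout.

    ``w_in`` has shape (n_hidden, n_in), ``v_rec`` (n_hidden, n_hidden) and
    is present iff ``recurrent``, ``w_out`` has shape (n_out, n_hidden).
    ``hidden_alpha``/``hidden_beta`` optionally override the scalar config
    decays with per-neuron vectors (heterogeneous, possibly trained, time
    constants).
    """

    n_in: int
    n_hidden: int
    n_out: int
    recurrent: bool
    w_in: np.ndarray
    w_out: np.ndarray
    hidden_cfg: NeuronModelConfig
    readout_cfg: NeuronModelConfig
    v_rec: Optional[np.ndarray] = None
    hidden_alpha: Optional[np.ndarray] = None
    hidden_beta: Optional[np.ndarray] = None
    zero_self_connections: bool = False

    def __post_init__(self):
        if self.w_in.shape != (self.n_hidden, self.n_in):
            raise ValueError(f"w_in shape {self.w_in.shape} != {(self.n_hidden, self.n_in)}")
        if self.w_out.shape != (self.n_out, self.n_hidden):
            raise ValueError(f"w_out shape {self.w_out.shape} != {(self.n_out, self.n_hidden)}")
        if self.recurrent:
            if self.v_rec is None:
                raise ValueError("recurrent network requires v_rec")
            if self.v_rec.shape != (self.n_hidden, self.n_hidden):
                raise ValueError("v_rec must be n_hidden x n_hidden")
        elif self.v_rec is not None:
            raise ValueError("v_rec present but recurrent flag is False")

    def effective_hidden_decays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-neuron (alpha, beta) vectors for the hidden layer."""
        a = (
            self.hidden_alpha
            if self.hidden_alpha is not None
            else np.full(self.n_hidden, self.hidden_cfg.alpha)
        )
        b = (
            self.hidden_beta
            if self.hidden_beta is not None
            else np.full(self.n_hidden, self.hidden_cfg.beta)
        )
        return np.asarray(a, dtype=float), np.asarray(b, dtype=float)

    def effective_v_rec(self) -> Optional[np.ndarray]:
        if not self.recurrent:
            return None
        v = self.v_rec
        if self.zero_self_connections:
            v = v.copy()
            np.fill_diagonal(v, 0.0)
        return v


@dataclass
class LayerState:
    """Per-neuron state carried between steps (shape = layer size, or
    (batch, layer size))."""

    i_syn: np.ndarray
    u_mem: np.ndarray
    s_prev: np.ndarray

    @classmethod
    def zeros(cls, *shape: int) -> "LayerState":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape))


@dataclass
class SimulationTrace:
    """Full record of one simulated batch.

    hidden_spikes: (n_steps, batch, n_hidden) binary
    readout_u:     (n_steps, batch, n_out)
    hidden_u / hidden_i: optional diagnostic trajectories, same layout.
    """

    hidden_spikes: np.ndarray
    readout_u: np.ndarray
    hidden_u: Optional[np.ndarray] = None
    hidden_i: Optional[np.ndarray] = None

    @property
    def n_steps(self) -> int:
        return self.hidden_spikes.shape[0]

    def to_table(self):
        """Columnar (step, sample, neuron, spike, u, i) export for debugging."""
        import pandas as pd

        t, b, h = self.hidden_spikes.shape
        idx = np.indices((t, b, h)).reshape(3, -1)
        cols = {
            "step": idx[0],
            "sample": idx[1],
            "neuron": idx[2],
            "spike": self.hidden_spikes.reshape(-1),
        }
        if self.hidden_u is not None:
            cols["u_mem"] = self.hidden_u.reshape(-1)
        if self.hidden_i is not None:
            cols["i_syn"] = self.hidden_i.reshape(-1)
        return pd.DataFrame(cols)


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite {what}")


def layer_step(
    state: LayerState,
    drive_ff: np.ndarray,
    drive_rec: Optional[np.ndarray],
    cfg: NeuronModelConfig,
    alpha: Optional[np.ndarray] = None,
    beta: Optional[np.ndarray] = None,
) -> tuple[LayerState, np.ndarray]:
    """Advance a spiking layer one step from the drives at t-1.

    ``drive_ff``/``drive_rec`` are the weighted spike sums
    ``W @ S^(l-1)[t-1]`` and ``V @ S^(l)[t-1]``.  Returns the new state and
    the binary spike vector S[t] (spike iff U[t] >= threshold).
    """
    _check_finite(drive_ff, "feedforward drive")
    a = cfg.alpha if alpha is None else alpha
    b = cfg.beta if beta is None else beta
    drive = drive_ff if drive_rec is None else drive_ff + drive_rec
    if drive_rec is not None:
        _check_finite(drive_rec, "recurrent drive")
    i_new = a * state.i_syn + drive
    u_new = (b * state.u_mem + i_new) * (1.0 - state.s_prev)
    spikes = (u_new >= cfg.threshold).astype(float)
    return LayerState(i_new, u_new, spikes), spikes


def readout_step(
    state: LayerState,
    drive_ff: np.ndarray,
    cfg: NeuronModelConfig,
) -> LayerState:
    """Advance the non-spiking readout: same updates, infinite threshold.

    No spike is ever emitted and the reset factor is identically 1, so the
    membrane is free to grow past the spiking layers' threshold.
    """
    _check_finite(drive_ff, "readout drive")
    i_new = cfg.alpha * state.i_syn + drive_ff
    u_new = cfg.beta * state.u_mem + i_new
    return LayerState(i_new, u_new, np.zeros_like(u_new))


def run_network(
    raster: np.ndarray,
    net: NetworkSpec,
    record_hidden_state: bool = False,
) -> SimulationTrace:
    """Simulate the full network over a binary input raster.

    ``raster`` is (n_steps, n_channels) for one sample or
    (n_steps, batch, n_channels) for a batch.  All states start at
    I = 0, U = U_rest = 0, S = 0; step t consumes input spikes and hidden
    spikes from step t-1 (the input frame at index t drives the states
    stored at index t, one step of axonal latency downstream).
    """
    x = np.asarray(raster, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, None, :]
    if x.ndim != 3 or x.shape[2] != net.n_in:
        raise ValueError(
            f"raster shape {raster.shape} incompatible with n_in={net.n_in}"
        )
    n_steps, batch, _ = x.shape
    alpha_h, beta_h = net.effective_hidden_decays()
    v = net.effective_v_rec()

    hid = LayerState.zeros(batch, net.n_hidden)
    out = LayerState.zeros(batch, net.n_out)
    hidden_spikes = np.zeros((n_steps, batch, net.n_hidden))
    readout_u = np.zeros((n_steps, batch, net.n_out))
    hidden_u = np.zeros_like(hidden_spikes) if record_hidden_state else None
    hidden_i = np.zeros_like(hidden_spikes) if record_hidden_state else None

    for t in range(n_steps):
        drive_ff = x[t] @ net.w_in.T
        drive_rec = hid.s_prev @ v.T if v is not None else None
        # readout drive uses hidden spikes at t-1, i.e. the pre-update state
        out_drive = hid.s_prev @ net.w_out.T
        hid, spikes = layer_step(hid, drive_ff, drive_rec, net.hidden_cfg, alpha_h, beta_h)
        out = readout_step(out, out_drive, net.readout_cfg)
        hidden_spikes[t] = spikes
        readout_u[t] = out.u_mem
        if record_hidden_state:
            hidden_u[t] = hid.u_mem
            hidden_i[t] = hid.i_syn

    if squeeze:
        hidden_spikes = hidden_spikes[:, 0]
        readout_u = readout_u[:, 0]
        if record_hidden_state:
            hidden_u = hidden_u[:, 0]
            hidden_i = hidden_i[:, 0]
    return SimulationTrace(hidden_spikes, readout_u, hidden_u, hidden_i)


def predict(trace: SimulationTrace) -> np.ndarray | int:
    """Predicted class: argmax over classes of the max-over-time readout
    membrane potential.  Ties break to the lowest class index (numpy argmax
    convention)."""
    u = trace.readout_u
    if u.size == 0:
        raise ValueError("empty trace")
    maxima = u.max(axis=0)  # (batch, n_out) or (n_out,)
    return np.argmax(maxima, axis=-1)
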