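"""Scalar reference interpreter for the neuron dynamics.

A deliberately naive, loop-per-neuron implementation of the same discrete
updates as :func:`leakysnn.dynamics.run_network`.  It serves two purposes:

* an independent cross-check of the vectorized simulator on small fixtures
  (the two must agree element-wise), and
* an instrumented mode that counts the arithmetic a per-neuron digital
  implementation would actually execute each step — multiplications by the
  decay constants, one addition per incoming spike (plus folding the
  current compartment into the membrane for CUBA-LIF), and one threshold
  comparison — so the per-neuron per-step operation budget of each model
  can be measured rather than asserted.

The reset gate ``(1 - S[t-1])`` is a select, not a multiplication, and is
not counted.  Only the spiking hidden layer is instrumented; the readout is
simulated but, being non-spiking, is outside the per-spiking-neuron
operation model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ModelKind, NetworkSpec, SimulationTrace

__all__ = ["StepCounts", "scalar_run"]


@dataclass
class StepCounts:
    """Per-step, per-hidden-neuron operation tallies (n_steps, n_hidden)."""

    multiplications: np.ndarray
    additions: np.ndarray
    comparisons: np.ndarray
    spiking_inputs: np.ndarray  # N*P: incoming spikes seen by each neuron


def scalar_run(
    raster: np.ndarray, net: NetworkSpec, count_ops: bool = False
) -> SimulationTrace | tuple[SimulationTrace, StepCounts]:
    """Simulate one sample with explicit scalar loops.

    ``raster`` is (n_steps, n_channels).  Returns the trace, and the
    operation tallies when ``count_ops`` is set.
    """
    x = np.asarray(raster, dtype=float)
    n_steps = x.shape[0]
    h, o = net.n_hidden, net.n_out
    kind = net.hidden_cfg.kind
    alpha_vec, beta_vec = net.effective_hidden_decays()
    a2, b2 = net.readout_cfg.alpha, net.readout_cfg.beta
    v = net.effective_v_rec()
    th = net.hidden_cfg.threshold

    i1 = [0.0] * h
    u1 = [0.0] * h
    s_prev = [0.0] * h
    i2 = [0.0] * o
    u2 = [0.0] * o

    hidden_spikes = np.zeros((n_steps, h))
    readout_u = np.zeros((n_steps, o))
    hidden_u = np.zeros((n_steps, h))
    hidden_i = np.zeros((n_steps, h))
    mults = np.zeros((n_steps, h))
    adds = np.zeros((n_steps, h))
    cmps = np.zeros((n_steps, h))
    n_spk_in = np.zeros((n_steps, h))

    for t in range(n_steps):
        new_i1, new_u1, new_s = [0.0] * h, [0.0] * h, [0.0] * h
        for n in range(h):
            a, b = alpha_vec[n], beta_vec[n]
            # accumulate one addition per incoming spike (feedforward and,
            # if recurrent, hidden spikes from the previous step)
            drive = 0.0
            spikes_in = 0
            for j in range(net.n_in):
                if x[t, j] != 0.0:
                    drive += net.w_in[n, j] * x[t, j]
                    spikes_in += 1
            if v is not None:
                for j in range(h):
                    if s_prev[j] != 0.0:
                        drive += v[n, j] * s_prev[j]
                        spikes_in += 1
            n_spk_in[t, n] = spikes_in
            adds[t, n] += spikes_in

            if kind is ModelKind.IF:
                # no current compartment, no leak: U accumulates the drive
                cur = drive
                u_pre = u1[n] + cur
            elif kind is ModelKind.LIF:
                # one multiplication: membrane leak
                cur = drive
                u_pre = b * u1[n] + cur
                mults[t, n] += 1
            else:  # CUBA-LIF: two multiplications and one extra addition
                cur = a * i1[n] + drive
                mults[t, n] += 1
                u_pre = b * u1[n] + cur
                mults[t, n] += 1
                adds[t, n] += 1  # folding I into the membrane update
            u_new = u_pre * (1.0 - s_prev[n])  # reset gate: select, not counted
            spike = 1.0 if u_new >= th else 0.0
            cmps[t, n] += 1
            new_i1[n], new_u1[n], new_s[n] = cur, u_new, spike

        new_i2, new_u2 = [0.0] * o, [0.0] * o
        for n in range(o):
            drive = 0.0
            for j in range(h):
                if s_prev[j] != 0.0:
                    drive += net.w_out[n, j] * s_prev[j]
            new_i2[n] = a2 * i2[n] + drive
            new_u2[n] = b2 * u2[n] + new_i2[n]

        i1, u1, s_prev = new_i1, new_u1, new_s
        i2, u2 = new_i2, new_u2
        hidden_spikes[t] = s_prev
        hidden_u[t] = u1
        hidden_i[t] = i1
        readout_u[t] = u2

    trace = SimulationTrace(hidden_spikes, readout_u, hidden_u, hidden_i)
    if count_ops:
        return trace, StepCounts(mults, adds, cmps, n_spk_in)
    return trace
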