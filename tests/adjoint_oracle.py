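"""Independent scalar chain-rule oracle for the surrogate-gradient BPTT.

This is a from-first-principles reimplementation used only by the tests: it
simulates one sample at a time with plain Python loops, stores every
intermediate, and then walks the unrolled computation graph backwards
accumulating adjoints neuron by neuron.  It shares no code with
``leakysnn.training.backward_pass`` (which is vectorized over batches); the
two must agree to tight relative tolerance on small random instances.

Convention under test: the spike derivative dS/dU is replaced by the
fast-sigmoid derivative 1/(1 + steep*|U - theta|)^2; the reset gate
(1 - S[t-1]) is a constant in the backward pass (no gradient through the
reset) unless ``grad_through_reset`` is set; the loss is the mean over
samples of the max-over-time softmax cross entropy.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_gradients(
    x: np.ndarray,
    labels: np.ndarray,
    w_in: np.ndarray,
    v_rec,
    w_out: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    alpha_out: float,
    beta_out: float,
    steepness: float = 100.0,
    threshold: float = 1.0,
    grad_through_reset: bool = False,
):
    """Gradients of the batch-mean loss w.r.t. all parameters.

    x: (T, B, n_in) binary; alpha/beta: per-hidden-neuron decay vectors.
    Returns a dict with keys w_in, v_rec (None if absent), w_out, alpha,
    beta, loss.
    """
    T, B, n_in = x.shape
    H = w_in.shape[0]
    O = w_out.shape[0]

    gw1 = np.zeros_like(w_in)
    gv = np.zeros_like(v_rec) if v_rec is not None else None
    gw2 = np.zeros_like(w_out)
    ga = np.zeros(H)
    gb = np.zeros(H)
    total_loss = 0.0

    for s_idx in range(B):
        xs = x[:, s_idx, :]
        # ---- scalar forward, storing everything -------------------------
        i1 = np.zeros((T, H))
        u1p = np.zeros((T, H))  # membrane before reset gate
        u1 = np.zeros((T, H))
        sp = np.zeros((T, H))
        i2 = np.zeros((T, O))
        u2 = np.zeros((T, O))
        for t in range(T):
            s_prev = sp[t - 1] if t > 0 else np.zeros(H)
            for n in range(H):
                drive = 0.0
                for j in range(n_in):
                    drive += w_in[n, j] * xs[t, j]
                if v_rec is not None:
                    for j in range(H):
                        drive += v_rec[n, j] * s_prev[j]
                i1[t, n] = alpha[n] * (i1[t - 1, n] if t > 0 else 0.0) + drive
                u1p[t, n] = beta[n] * (u1[t - 1, n] if t > 0 else 0.0) + i1[t, n]
                u1[t, n] = u1p[t, n] * (1.0 - s_prev[n])
                sp[t, n] = 1.0 if u1[t, n] >= threshold else 0.0
            for n in range(O):
                drive = 0.0
                for j in range(H):
                    drive += w_out[n, j] * s_prev[j]
                i2[t, n] = alpha_out * (i2[t - 1, n] if t > 0 else 0.0) + drive
                u2[t, n] = beta_out * (u2[t - 1, n] if t > 0 else 0.0) + i2[t, n]

        # ---- loss: softmax CE on per-class max-over-time ----------------
        m = u2.max(axis=0)
        t_star = u2.argmax(axis=0)
        z = m - m.max()
        p = np.exp(z) / np.exp(z).sum()
        y = int(labels[s_idx])
        total_loss += -math.log(p[y])
        dm = p.copy()
        dm[y] -= 1.0
        dm /= B  # batch-mean prefactor

        # ---- adjoints, walked backwards step by step --------------------
        dU2 = np.zeros((T, O))
        dI2 = np.zeros((T, O))
        dU1 = np.zeros((T, H))
        dI1 = np.zeros((T, H))
        dS = np.zeros((T, H))
        for t in range(T - 1, -1, -1):
            for n in range(O):
                dU2[t, n] = (beta_out * dU2[t + 1, n] if t + 1 < T else 0.0)
                if t_star[n] == t:
                    dU2[t, n] += dm[n]
                dI2[t, n] = dU2[t, n] + (alpha_out * dI2[t + 1, n] if t + 1 < T else 0.0)
            s_prev = sp[t - 1] if t > 0 else np.zeros(H)
            for n in range(H):
                # spike S[t, n] is consumed at t+1 by: readout drive,
                # recurrent drive, and (optionally) the reset gate
                acc = 0.0
                if t + 1 < T:
                    for k in range(O):
                        acc += w_out[k, n] * dI2[t + 1, k]
                    if v_rec is not None:
                        for k in range(H):
                            acc += v_rec[k, n] * dI1[t + 1, k]
                    if grad_through_reset:
                        acc -= u1p[t + 1, n] * dU1[t + 1, n]
                dS[t, n] = acc
                surr = 1.0 / (1.0 + steepness * abs(u1[t, n] - threshold)) ** 2
                carry = 0.0
                if t + 1 < T:
                    carry = beta[n] * dU1[t + 1, n] * (1.0 - sp[t, n])
                dU1[t, n] = surr * dS[t, n] + carry
                dI1[t, n] = dU1[t, n] * (1.0 - s_prev[n]) + (
                    alpha[n] * dI1[t + 1, n] if t + 1 < T else 0.0
                )

        # ---- parameter gradients ----------------------------------------
        for t in range(T):
            s_prev = sp[t - 1] if t > 0 else np.zeros(H)
            for n in range(H):
                for j in range(n_in):
                    gw1[n, j] += dI1[t, n] * xs[t, j]
                if gv is not None:
                    for j in range(H):
                        gv[n, j] += dI1[t, n] * s_prev[j]
                if t > 0:
                    ga[n] += dI1[t, n] * i1[t - 1, n]
                    gb[n] += dU1[t, n] * (1.0 - s_prev[n]) * u1[t - 1, n]
            for n in range(O):
                for j in range(H):
                    gw2[n, j] += dI2[t, n] * s_prev[j]

    return {
        "w_in": gw1,
        "v_rec": gv,
        "w_out": gw2,
        "alpha": ga,
        "beta": gb,
        "loss": total_loss / B,
    }
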