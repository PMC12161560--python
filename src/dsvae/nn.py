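"""Minimal neural-network kernel on top of autograd/numpy.

Parameters are nested dicts of float64 numpy arrays; forward passes are
written with :mod:`autograd.numpy` so gradients come from reverse-mode
autodiff. Everything is batched over the leading axis; only the recurrent
time loops are sequential. The Adam optimizer operates on the flattened
parameter vector.
"""
from __future__ import annotations

import autograd.numpy as anp
import numpy as np

LOGVAR_MIN, LOGVAR_MAX = -10.0, 10.0


def clamp_logvar(lv):
    """Clamp log-variances to [-10, 10] to keep KL terms finite."""
    return anp.clip(lv, LOGVAR_MIN, LOGVAR_MAX)


def sigmoid(x):
    # tanh-based form is numerically stable at both tails
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


# ---------------------------------------------------------------------------
# Initializers
# ---------------------------------------------------------------------------

def _glorot(rng, shape):
    scale = np.sqrt(2.0 / (shape[0] + shape[1]))
    return rng.standard_normal(shape) * scale


def init_dense(rng, d_in, d_out):
    return {"W": _glorot(rng, (d_in, d_out)), "b": np.zeros(d_out)}


def init_rnn_cell(rng, d_in, d_hidden):
    return {
        "Wx": _glorot(rng, (d_in, d_hidden)),
        "Wh": _glorot(rng, (d_hidden, d_hidden)),
        "b": np.zeros(d_hidden),
    }


def init_gru_cell(rng, d_in, d_hidden):
    return {
        "Wx": _glorot(rng, (d_in, 3 * d_hidden)),
        "Wh": _glorot(rng, (d_hidden, 3 * d_hidden)),
        "b": np.zeros(3 * d_hidden),
    }


def init_conv1d(rng, d_in, d_out, kernel=5):
    scale = np.sqrt(2.0 / (kernel * d_in + d_out))
    return {"K": rng.standard_normal((kernel, d_in, d_out)) * scale, "b": np.zeros(d_out)}


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def dense(p, x):
    return x @ p["W"] + p["b"]


def rnn_step(p, x, h):
    """Elman (tanh) recurrence."""
    return anp.tanh(x @ p["Wx"] + h @ p["Wh"] + p["b"])


def gru_step(p, x, h):
    """Standard GRU cell; gate order along the last axis is (reset, update,
    candidate)."""
    dh = p["Wh"].shape[0]
    gx = x @ p["Wx"] + p["b"]
    gh = h @ p["Wh"]
    r = sigmoid(gx[:, :dh] + gh[:, :dh])
    u = sigmoid(gx[:, dh : 2 * dh] + gh[:, dh : 2 * dh])
    n = anp.tanh(gx[:, 2 * dh :] + r * gh[:, 2 * dh :])
    return (1.0 - u) * n + u * h


def birnn(p, X, Wx=None, extra_proj=None):
    """Bidirectional tanh RNN over data X of shape (B, T, D).

    ``p`` has sub-dicts ``fw`` and ``bw``. Returns (states, final):
    states is (B, T, 2H) with forward and backward states concatenated per
    timestep; final is (B, 2H), the last state of each direction.

    X is expected to be a plain (untraced) numpy array, so the per-step
    slices below cost nothing in the autodiff graph; both directions run
    through one batched matrix product per step. ``Wx`` optionally
    overrides the stacked (2, D, H) input weights and ``extra_proj``
    (broadcastable to (2, B, H)) adds a per-window input projection shared
    across timesteps — this is how a context sample is
    broadcast-concatenated to every timestep without re-projecting it per
    step.
    """
    X = np.asarray(X)
    B, T, D = X.shape
    H = p["fw"]["Wh"].shape[0]
    if Wx is None:
        Wx = anp.stack([p["fw"]["Wx"], p["bw"]["Wx"]])  # (2, D, H)
    Wh = anp.stack([p["fw"]["Wh"], p["bw"]["Wh"]])  # (2, H, H)
    base = anp.stack([p["fw"]["b"], p["bw"]["b"]])[:, None, :]  # (2, 1, H)
    if extra_proj is not None:
        base = base + extra_proj
    # per-step (2, B, D) input pairs: forward reads t, backward reads T-1-t
    x_steps = [np.stack([X[:, t], X[:, T - 1 - t]]) for t in range(T)]
    h = anp.zeros((2, B, H))
    states = []
    for t in range(T):
        h = anp.tanh(anp.matmul(x_steps[t], Wx) + base + anp.matmul(h, Wh))
        states.append(h)
    S = anp.stack(states)  # (T, 2, B, H)
    fw = anp.transpose(S[:, 0], (1, 0, 2))
    bw = anp.transpose(S[::-1, 1], (1, 0, 2))
    states_out = anp.concatenate([fw, bw], axis=2)
    final = anp.concatenate([h[0], h[1]], axis=1)
    return states_out, final


def conv1d_same(p, X):
    """1-D convolution along the time axis with zero 'same' padding.

    X is (B, T, D_in); kernel K is (k, D_in, D_out). Implemented as a sum of
    k shifted matrix products, which keeps the autodiff graph small.
    """
    k = p["K"].shape[0]
    B, T, _ = X.shape
    left = (k - 1) // 2
    right = k - 1 - left
    Xp = anp.concatenate(
        [anp.zeros((B, left, X.shape[2])), X, anp.zeros((B, right, X.shape[2]))],
        axis=1,
    )
    out = p["b"]
    for i in range(k):
        out = out + Xp[:, i : i + T, :] @ p["K"][i]
    return out


def relu(x):
    return anp.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam on a flat parameter vector (float64, deterministic)."""

    def __init__(self, learning_rate=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, flat_params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(flat_params)
            self.v = np.zeros_like(flat_params)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        return flat_params - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def count_params(tree) -> int:
    if isinstance(tree, dict):
        return sum(count_params(v) for v in tree.values())
    return int(np.asarray(tree).size)
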