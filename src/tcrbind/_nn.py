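"""Minimal numpy neural-network kernels for the two scorer families.

Implements exactly the pieces the scorers need — an embedding + LSTM
encoder, a one-hot convolution + global-max-pool encoder, a fully
connected head with dropout, binary cross-entropy with logits, and Adam —
with hand-derived backward passes. Everything is float64 and fully
deterministic given a seeded ``numpy.random.Generator``; correctness of
every backward pass is pinned by finite-difference tests.

Parameter archives are flat ``dict[str, ndarray]`` with dotted names whose
first component is the layer group (``cdr3_encoder``, ``peptide_encoder``,
``head``) used for parameter freezing during fine-tuning.
"""

from __future__ import annotations

import numpy as np

LAYER_GROUPS = ("cdr3_encoder", "peptide_encoder", "head")


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    n = logits.shape[0]
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    dlogits = (sigmoid(logits) - y) / n
    return loss, dlogits


# --------------------------------------------------------------------------
# LSTM encoder (embedding -> masked LSTM -> final hidden state)
# --------------------------------------------------------------------------

def init_lstm_branch(rng, prefix, embed_dim, hidden_dim):
    emb = glorot(rng, (21, embed_dim))
    emb[0] = 0.0  # pad row
    p = {
        f"{prefix}.embed": emb,
        f"{prefix}.Wx": glorot(rng, (embed_dim, 4 * hidden_dim)),
        f"{prefix}.Wh": glorot(rng, (hidden_dim, 4 * hidden_dim)),
        f"{prefix}.b": np.zeros(4 * hidden_dim),
    }
    # forget-gate bias 1.0: standard stabilization for short sequences
    p[f"{prefix}.b"][hidden_dim:2 * hidden_dim] = 1.0
    return p


def lstm_forward(params, prefix, idx, lengths):
    """Run a masked LSTM over index vectors; returns (final_h, cache).

    Padded timesteps carry the previous hidden/cell state forward, so the
    final state equals the state at each sequence's true last residue.
    """
    emb = params[f"{prefix}.embed"]
    Wx, Wh, b = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"], params[f"{prefix}.b"]
    B, T = idx.shape
    H = Wh.shape[0]
    x = emb[idx]                                   # (B, T, E)
    xp = x.reshape(B * T, -1) @ Wx                 # one big GEMM
    xp = xp.reshape(B, T, 4 * H) + b
    mask = (np.arange(T)[None, :] < lengths[:, None]).astype(np.float64)

    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    for t in range(T):
        a = xp[:, t] + h @ Wh
        i = sigmoid(a[:, :H])
        f = sigmoid(a[:, H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = sigmoid(a[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        m = mask[:, t:t + 1]
        steps.append((i, f, g, o, tc, c, h, m))
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
    cache = {"idx": idx, "x": x, "steps": steps, "H": H, "prefix": prefix}
    return h, cache


def lstm_backward(params, cache, dh_final):
    prefix, H = cache["prefix"], cache["H"]
    Wx, Wh = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"]
    idx, x, steps = cache["idx"], cache["x"], cache["steps"]
    B, T, E = x.shape

    dWh = np.zeros_like(Wh)
    dxp = np.zeros((B, T, 4 * H))
    dh = dh_final.copy()
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o, tc, c_prev, h_prev, m = steps[t]
        dh_new = m * dh
        dc_t = m * dc
        dh_prev = (1.0 - m) * dh
        dc_prev_carry = (1.0 - m) * dc

        do = dh_new * tc
        dc_t = dc_t + dh_new * o * (1.0 - tc * tc)
        df = dc_t * c_prev
        di = dc_t * g
        dg = dc_t * i
        dc_prev = dc_t * f

        da = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ], axis=1)
        dxp[:, t] = da
        dWh += h_prev.T @ da
        dh = dh_prev + da @ Wh.T
        dc = dc_prev_carry + dc_prev

    dxp_flat = dxp.reshape(B * T, 4 * H)
    dWx = x.reshape(B * T, E).T @ dxp_flat
    db = dxp_flat.sum(axis=0)
    dx = (dxp_flat @ Wx.T).reshape(B, T, E)
    demb = np.zeros_like(params[f"{prefix}.embed"])
    np.add.at(demb, idx.reshape(-1), dx.reshape(-1, E))
    demb[0] = 0.0  # pad embedding stays fixed
    return {
        f"{prefix}.embed": demb,
        f"{prefix}.Wx": dWx,
        f"{prefix}.Wh": dWh,
        f"{prefix}.b": db,
    }


# --------------------------------------------------------------------------
# Convolutional encoder (one-hot -> multi-width conv -> ReLU -> max pool)
# --------------------------------------------------------------------------

def init_conv_branch(rng, prefix, filter_sizes, channels):
    p = {}
    for k in filter_sizes:
        p[f"{prefix}.conv{k}.W"] = glorot(rng, (k * 20, channels))
        p[f"{prefix}.conv{k}.b"] = np.zeros(channels)
    return p


def conv_forward(params, prefix, oh, lengths, filter_sizes):
    """Multi-width 1-D convolution over one-hot input with masked global
    max pooling; windows overlapping padding are excluded from the max."""
    B, L, _ = oh.shape
    outs, caches = [], []
    for k in filter_sizes:
        P = L - k + 1
        win = np.lib.stride_tricks.sliding_window_view(oh, k, axis=1)  # (B,P,20,k)
        Xw = win.transpose(0, 1, 3, 2).reshape(B, P, k * 20)
        W, b = params[f"{prefix}.conv{k}.W"], params[f"{prefix}.conv{k}.b"]
        Z = Xw @ W + b                                                 # (B,P,C)
        A = np.maximum(Z, 0.0)
        valid = (np.arange(P)[None, :] + k) <= lengths[:, None]        # (B,P)
        Am = np.where(valid[:, :, None], A, -np.inf)
        arg = Am.argmax(axis=1)                                        # (B,C)
        outs.append(np.take_along_axis(Am, arg[:, None, :], axis=1)[:, 0, :])
        caches.append({"Xw": Xw, "Z": Z, "arg": arg, "k": k})
    return np.concatenate(outs, axis=1), {"caches": caches, "prefix": prefix}


def conv_backward(params, cache, dout):
    prefix = cache["prefix"]
    grads = {}
    col = 0
    for c in cache["caches"]:
        Xw, Z, arg, k = c["Xw"], c["Z"], c["arg"], c["k"]
        B, P, C = Z.shape
        d_k = dout[:, col:col + C]
        col += C
        dA = np.zeros((B, P, C))
        np.put_along_axis(dA, arg[:, None, :], d_k[:, None, :], axis=1)
        dZ = dA * (Z > 0.0)
        grads[f"{prefix}.conv{k}.W"] = Xw.reshape(B * P, -1).T @ dZ.reshape(B * P, C)
        grads[f"{prefix}.conv{k}.b"] = dZ.sum(axis=(0, 1))
    return grads


# --------------------------------------------------------------------------
# Fully connected head
# --------------------------------------------------------------------------

def init_head(rng, in_dim, layer_widths):
    p = {}
    dims = [in_dim, *layer_widths, 1]
    for j in range(len(dims) - 1):
        p[f"head.W{j}"] = glorot(rng, (dims[j], dims[j + 1]))
        p[f"head.b{j}"] = np.zeros(dims[j + 1])
    return p


def head_forward(params, h0, n_hidden, dropout=0.0, rng=None):
    """ReLU MLP ending in a single linear logit; inverted dropout after
    each hidden activation when training (rng given and dropout > 0)."""
    acts = [h0]
    masks = []
    zs = []
    h = h0
    for j in range(n_hidden + 1):
        z = h @ params[f"head.W{j}"] + params[f"head.b{j}"]
        zs.append(z)
        if j < n_hidden:
            h = np.maximum(z, 0.0)
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(h)
    logits = zs[-1][:, 0]
    return logits, {"acts": acts, "zs": zs, "masks": masks, "n_hidden": n_hidden}


def head_backward(params, cache, dlogits):
    acts, zs, masks, n_hidden = cache["acts"], cache["zs"], cache["masks"], cache["n_hidden"]
    grads = {}
    d = dlogits[:, None]
    for j in range(n_hidden, -1, -1):
        grads[f"head.b{j}"] = d.sum(axis=0)
        grads[f"head.W{j}"] = acts[j].T @ d
        d = d @ params[f"head.W{j}"].T
        if j > 0:
            if masks[j - 1] is not None:
                d = d * masks[j - 1]
            d = d * (zs[j - 1] > 0.0)
    return grads, d  # d is now the gradient wrt the head input


# --------------------------------------------------------------------------
# Adam
# --------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a named parameter archive."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, frozen: frozenset = frozenset()):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            if k.split(".", 1)[0] in frozen:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
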