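"""Numpy core of the gated recurrent classifier.

A stack of GRU layers reads the 7-step, 10-channel monthly sequence; two
dense layers map the final hidden state to per-class sigmoid scores which
are row-normalized into probabilities.  The update equations, with sigmoid
``s`` and elementwise products:

    z_t = s(x_t W_z + h_{t-1} U_z + b_z)          (update gate)
    r_t = s(x_t W_r + h_{t-1} U_r + b_r)          (reset gate)
    n_t = tanh(x_t W_n + (r_t * h_{t-1}) U_n + b_n)
    h_t = (1 - z_t) * h_{t-1} + z_t * n_t

(z gates the *new* candidate here; equivalent to the common convention with
z replaced by 1-z.)  Head: f = relu(h_T W_1 + b_1) is the deep feature used
by the center loss; scores = s(f W_2 + b_2); p = scores / sum(scores).

Everything is a pure function of a parameter dict so the backward pass can
be checked against numerical differentiation.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def init_params(
    input_dim: int,
    hidden_size: int,
    n_classes: int,
    n_layers: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases."""
    params: dict[str, np.ndarray] = {}

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, size=shape)

    for layer in range(n_layers):
        d = input_dim if layer == 0 else hidden_size
        for gate in ("z", "r", "n"):
            params[f"W_{gate}{layer}"] = glorot((d, hidden_size))
            params[f"U_{gate}{layer}"] = glorot((hidden_size, hidden_size))
            params[f"b_{gate}{layer}"] = np.zeros(hidden_size)
    params["W1"] = glorot((hidden_size, hidden_size))
    params["b1"] = np.zeros(hidden_size)
    params["W2"] = glorot((hidden_size, n_classes))
    params["b2"] = np.zeros(n_classes)
    return params


def n_layers_of(params: dict[str, np.ndarray]) -> int:
    return 1 + max(int(k[3:]) for k in params if k.startswith("W_z"))


def forward(params: dict[str, np.ndarray], X: np.ndarray) -> dict:
    """Run the network; returns probabilities, features and per-step caches."""
    X = np.asarray(X, dtype=float)
    n, t, _ = X.shape
    layers = n_layers_of(params)
    hidden = params["b_z0"].shape[0]
    cache: dict = {"X": X, "steps": [], "h_last": []}
    inp = X
    for layer in range(layers):
        h = np.zeros((n, hidden))
        outs = np.empty((n, t, hidden))
        steps = []
        for k in range(t):
            x = inp[:, k, :]
            z = _sigmoid(x @ params[f"W_z{layer}"] + h @ params[f"U_z{layer}"]
                         + params[f"b_z{layer}"])
            r = _sigmoid(x @ params[f"W_r{layer}"] + h @ params[f"U_r{layer}"]
                         + params[f"b_r{layer}"])
            rh = r * h
            nn = np.tanh(x @ params[f"W_n{layer}"] + rh @ params[f"U_n{layer}"]
                         + params[f"b_n{layer}"])
            h_new = (1.0 - z) * h + z * nn
            steps.append({"x": x, "h_prev": h, "z": z, "r": r, "n": nn})
            outs[:, k, :] = h_new
            h = h_new
        cache["steps"].append(steps)
        cache["h_last"].append(h)
        inp = outs
    a1 = cache["h_last"][-1] @ params["W1"] + params["b1"]
    f = np.maximum(a1, 0.0)
    scores = _sigmoid(f @ params["W2"] + params["b2"])
    probs = scores / np.maximum(scores.sum(axis=1, keepdims=True), EPS)
    cache.update(a1=a1, features=f, scores=scores, probs=probs)
    return cache


def losses(
    cache: dict, y_idx: np.ndarray, centers: np.ndarray
) -> tuple[float, float]:
    """(cross-entropy averaged over the batch, center loss summed over it)."""
    n = cache["probs"].shape[0]
    p_true = np.clip(cache["probs"][np.arange(n), y_idx], EPS, 1.0)
    ce = float(-np.mean(np.log(p_true)))
    diff = cache["features"] - centers[y_idx]
    center = float(0.5 * np.sum(diff * diff))
    return ce, center


def backward(
    params: dict[str, np.ndarray],
    cache: dict,
    y_idx: np.ndarray,
    centers: np.ndarray,
    w1: float,
    w2: float,
) -> dict[str, np.ndarray]:
    """Gradients of w1*CE + w2*center w.r.t. every parameter."""
    n = cache["probs"].shape[0]
    scores, f = cache["scores"], cache["features"]
    S = np.maximum(scores.sum(axis=1, keepdims=True), EPS)
    onehot = np.zeros_like(scores)
    onehot[np.arange(n), y_idx] = 1.0
    # d(CE)/d(scores): log p_y = log s_y - log S
    dscores = (1.0 / S - onehot / np.clip(scores, EPS, None)) * (w1 / n)
    da2 = dscores * scores * (1.0 - scores)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["W2"] = f.T @ da2
    grads["b2"] = da2.sum(axis=0)
    df = da2 @ params["W2"].T + w2 * (f - centers[y_idx])
    da1 = df * (cache["a1"] > 0)
    h_last = cache["h_last"][-1]
    grads["W1"] = h_last.T @ da1
    grads["b1"] = da1.sum(axis=0)

    layers = n_layers_of(params)
    t = cache["X"].shape[1]
    # per-step gradient flowing into each layer's outputs
    dout = np.zeros((n, t, h_last.shape[1]))
    dout[:, -1, :] = da1 @ params["W1"].T
    for layer in range(layers - 1, -1, -1):
        steps = cache["steps"][layer]
        d_in = np.zeros(
            cache["X"].shape if layer == 0 else (n, t, h_last.shape[1])
        )
        dh = np.zeros_like(h_last)
        for k in range(t - 1, -1, -1):
            dh = dh + dout[:, k, :]
            st = steps[k]
            z, r, nn, h_prev, x = st["z"], st["r"], st["n"], st["h_prev"], st["x"]
            dn = dh * z
            dz = dh * (nn - h_prev)
            dh_prev = dh * (1.0 - z)
            da_n = dn * (1.0 - nn * nn)
            grads[f"W_n{layer}"] += x.T @ da_n
            grads[f"U_n{layer}"] += (r * h_prev).T @ da_n
            grads[f"b_n{layer}"] += da_n.sum(axis=0)
            drh = da_n @ params[f"U_n{layer}"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            grads[f"W_z{layer}"] += x.T @ da_z
            grads[f"U_z{layer}"] += h_prev.T @ da_z
            grads[f"b_z{layer}"] += da_z.sum(axis=0)
            grads[f"W_r{layer}"] += x.T @ da_r
            grads[f"U_r{layer}"] += h_prev.T @ da_r
            grads[f"b_r{layer}"] += da_r.sum(axis=0)
            dx = (da_z @ params[f"W_z{layer}"].T
                  + da_r @ params[f"W_r{layer}"].T
                  + da_n @ params[f"W_n{layer}"].T)
            d_in[:, k, :] = dx
            dh_prev = dh_prev + (da_z @ params[f"U_z{layer}"].T
                                 + da_r @ params[f"U_r{layer}"].T)
            dh = dh_prev
        dout = d_in  # becomes the per-step gradient for the layer below
    return grads


class Adam:
    """Plain Adam over a parameter dict."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
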