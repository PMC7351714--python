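"""Stacked LSTM binary classifier with manual backpropagation.

Architecture: two LSTM layers (60 units each by default) over an input of
shape [timesteps, 3], a dropout of 0.4 on the final hidden state, and a
sigmoid dense head emitting one probability per window. Gates follow the
standard formulation (input, forget, cell candidate, output; forget-gate
bias initialized at 1).
"""

from __future__ import annotations

import copy

import numpy as np

from .core import dropout_mask, glorot_uniform, sigmoid


class LSTMClassifier:
    """Stacked-LSTM probability-of-event classifier.

    Parameters are plain NumPy arrays in ``self.params``; ``forward``
    returns probabilities and a cache that ``backward`` consumes to produce
    exact gradients (verified against finite differences in the test
    suite).
    """

    def __init__(
        self,
        timesteps: int,
        n_features: int = 3,
        units: tuple[int, ...] = (60, 60),
        dropout: float = 0.4,
        seed: int = 0,
    ):
        self.timesteps = timesteps
        self.n_features = n_features
        self.units = tuple(units)
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        in_dim = n_features
        for layer, H in enumerate(self.units):
            self.params[f"Wx{layer}"] = glorot_uniform(rng, (in_dim, 4 * H))
            self.params[f"Wh{layer}"] = glorot_uniform(rng, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b{layer}"] = b
            in_dim = H
        self.params["Wd"] = glorot_uniform(rng, (in_dim, 1))
        self.params["bd"] = np.zeros(1)

    # ------------------------------------------------------------------
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def get_params(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.params)

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = copy.deepcopy(params)

    def clone(self) -> "LSTMClassifier":
        out = LSTMClassifier(
            self.timesteps, self.n_features, self.units, self.dropout, seed=0
        )
        out.set_params(self.params)
        return out

    # ------------------------------------------------------------------
    def _layer_forward(self, X: np.ndarray, layer: int):
        """Run one LSTM layer over [B, T, in]; return hidden sequence + cache."""
        Wx = self.params[f"Wx{layer}"]
        Wh = self.params[f"Wh{layer}"]
        b = self.params[f"b{layer}"]
        B, T, _ = X.shape
        H = Wh.shape[0]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        steps = []
        for t in range(T):
            a = X[:, t, :] @ Wx + h @ Wh + b
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = sigmoid(a[:, 3 * H :])
            c_next = f * c + i * g
            tc = np.tanh(c_next)
            h_next = o * tc
            steps.append((X[:, t, :], h, c, i, f, g, o, c_next, tc))
            h, c = h_next, c_next
            hs[:, t, :] = h
        return hs, steps

    def _layer_backward(self, steps, dh_seq: np.ndarray, layer: int):
        """Backprop one layer given per-step output gradients [B, T, H]."""
        Wx = self.params[f"Wx{layer}"]
        Wh = self.params[f"Wh{layer}"]
        B, T, H = dh_seq.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dX = np.zeros((B, T, Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = steps[t]
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t, :] = da @ Wx.T
            dh_next = da @ Wh.T
        return dX, {f"Wx{layer}": dWx, f"Wh{layer}": dWh, f"b{layer}": db}

    # ------------------------------------------------------------------
    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Probabilities for a batch [B, T, F]; returns (probs, cache)."""
        X = np.asarray(X, dtype=float)
        caches = []
        out = X
        for layer in range(len(self.units)):
            out, steps = self._layer_forward(out, layer)
            caches.append(steps)
        h_last = out[:, -1, :]
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            dmask = dropout_mask(rng, h_last.shape, self.dropout)
        else:
            dmask = np.ones_like(h_last)
        h_drop = h_last * dmask
        logits = h_drop @ self.params["Wd"] + self.params["bd"]
        probs = sigmoid(logits).ravel()
        cache = (caches, h_drop, dmask, X.shape)
        return probs, cache

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients given d(loss)/d(logit) of shape [B]."""
        caches, h_drop, dmask, shape = cache
        B, T, _ = shape
        dlog = np.asarray(dlogits, dtype=float).reshape(B, 1)
        grads = {
            "Wd": h_drop.T @ dlog,
            "bd": dlog.sum(axis=0),
        }
        dh_last = (dlog @ self.params["Wd"].T) * dmask
        top = len(self.units) - 1
        dh_seq = np.zeros((B, T, self.units[top]))
        dh_seq[:, -1, :] = dh_last
        dX = dh_seq
        for layer in reversed(range(len(self.units))):
            if layer != top:
                dh_seq = dX
            dX, layer_grads = self._layer_backward(caches[layer], dh_seq, layer)
            grads.update(layer_grads)
        return grads

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Inference probabilities, batch-size invariant."""
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for start in range(0, len(X), batch_size):
            probs, _ = self.forward(X[start : start + batch_size], train=False)
            out[start : start + batch_size] = probs
        return out

    def inputs_from(self, dataset) -> np.ndarray:
        """The model's input tensor from a :class:`WindowDataset`."""
        return dataset.X
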