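"""Gated recurrent unit with trainable decay for missing clinical data.

The cell consumes three aligned inputs per window: the unfilled values, an
observation mask, and the per-channel time since the last observation. Two
trainable exponential decays act on them:

* **input decay** ``gamma_x = exp(-max(0, w_x * delta + b_x))`` (one weight
  per channel) relaxes an unobserved channel from its last observed value
  toward the training-set channel mean;
* **hidden decay** ``gamma_h = exp(-max(0, W_h delta + b_h))`` shrinks the
  hidden state before each update when observations are stale.

The mask is also fed to every gate as an extra input. With all-ones masks,
unit deltas and zeroed decay and mask parameters, the cell's hidden
trajectory equals a standard gated recurrent unit's (checked in tests).
"""

from __future__ import annotations

import copy

import numpy as np

from .core import dropout_mask, glorot_uniform, sigmoid


class GRUDClassifier:
    """Single-layer decay-GRU (100 units by default) with a sigmoid head."""

    GATES = ("r", "z", "h")

    def __init__(
        self,
        timesteps: int,
        n_features: int = 3,
        units: int = 100,
        dropout: float = 0.3,
        seed: int = 0,
    ):
        self.timesteps = timesteps
        self.n_features = n_features
        self.units = units
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        D, H = n_features, units
        self.params: dict[str, np.ndarray] = {}
        for gate in self.GATES:
            self.params[f"Wx{gate}"] = glorot_uniform(rng, (D, H))
            self.params[f"Wh{gate}"] = glorot_uniform(rng, (H, H))
            self.params[f"Wm{gate}"] = glorot_uniform(rng, (D, H))
            self.params[f"b{gate}"] = np.zeros(H)
        self.params["wgx"] = np.zeros(D)
        self.params["bgx"] = np.zeros(D)
        self.params["Wgh"] = np.zeros((D, H))
        self.params["bgh"] = np.zeros(H)
        self.params["Wd"] = glorot_uniform(rng, (H, 1))
        self.params["bd"] = np.zeros(1)
        # non-trainable: empirical channel means of the training set
        # (mid-range in normalized units until fit sets them)
        self.x_mean = np.full(D, 0.5)

    # ------------------------------------------------------------------
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def get_params(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.params)

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = copy.deepcopy(params)

    def clone(self) -> "GRUDClassifier":
        out = GRUDClassifier(
            self.timesteps, self.n_features, self.units, self.dropout, seed=0
        )
        out.set_params(self.params)
        out.x_mean = self.x_mean.copy()
        return out

    def set_feature_means(self, means: np.ndarray) -> None:
        self.x_mean = np.asarray(means, dtype=float).copy()

    # ------------------------------------------------------------------
    def forward(
        self,
        inputs: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Probabilities for a batch of (values, mask, delta, last_observed).

        Each array has shape [B, T, D]; ``last_observed`` may hold NaN for
        channels not yet observed, which fall back to the channel mean.
        """
        values, mask, delta, x_last = (np.asarray(a, dtype=float) for a in inputs)
        if not values.shape == mask.shape == delta.shape == x_last.shape:
            raise ValueError("decay-model inputs must share one shape")
        B, T, D = values.shape
        H = self.units
        p = self.params
        xl_eff = np.where(np.isnan(x_last), self.x_mean, x_last)
        h = np.zeros((B, H))
        steps = []
        for t in range(T):
            x, m, d, xl = values[:, t], mask[:, t], delta[:, t], xl_eff[:, t]
            gx_pre = d * p["wgx"] + p["bgx"]
            gx = np.exp(-np.maximum(0.0, gx_pre))
            xhat = m * x + (1.0 - m) * (gx * xl + (1.0 - gx) * self.x_mean)
            gh_pre = d @ p["Wgh"] + p["bgh"]
            gh = np.exp(-np.maximum(0.0, gh_pre))
            h_prev = h
            h_dec = gh * h_prev
            r = sigmoid(xhat @ p["Wxr"] + h_dec @ p["Whr"] + m @ p["Wmr"] + p["br"])
            z = sigmoid(xhat @ p["Wxz"] + h_dec @ p["Whz"] + m @ p["Wmz"] + p["bz"])
            htil = np.tanh(
                xhat @ p["Wxh"] + (r * h_dec) @ p["Whh"] + m @ p["Wmh"] + p["bh"]
            )
            h = (1.0 - z) * h_dec + z * htil
            steps.append(
                (x, m, d, xl, gx, gx_pre > 0, xhat, gh, gh_pre > 0, h_prev, h_dec, r, z, htil)
            )
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            dmask = dropout_mask(rng, h.shape, self.dropout)
        else:
            dmask = np.ones_like(h)
        h_drop = h * dmask
        logits = h_drop @ p["Wd"] + p["bd"]
        probs = sigmoid(logits).ravel()
        return probs, (steps, h_drop, dmask, (B, T, D))

    def hidden_trajectory(self, inputs) -> np.ndarray:
        """[B, T, H] hidden states (for cell-level equivalence checks)."""
        values, mask, delta, x_last = (np.asarray(a, dtype=float) for a in inputs)
        _, cache = self.forward((values, mask, delta, x_last), train=False)
        steps = cache[0]
        B, T, _ = values.shape
        out = np.zeros((B, T, self.units))
        for t, step in enumerate(steps):
            _, m, d, xl, gx, _, xhat, gh, _, h_prev, h_dec, r, z, htil = step
            out[:, t] = (1.0 - z) * h_dec + z * htil
        return out

    # ------------------------------------------------------------------
    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        steps, h_drop, dmask, (B, T, D) = cache
        p = self.params
        H = self.units
        dlog = np.asarray(dlogits, dtype=float).reshape(B, 1)
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wd"] = h_drop.T @ dlog
        grads["bd"] = dlog.sum(axis=0)
        dh = (dlog @ p["Wd"].T) * dmask
        for t in reversed(range(T)):
            (x, m, d, xl, gx, gx_pos, xhat, gh, gh_pos, h_prev, h_dec, r, z, htil) = steps[t]
            dz = dh * (htil - h_dec)
            dhtil = dh * z
            dh_dec = dh * (1.0 - z)

            da_h = dhtil * (1.0 - htil * htil)
            dxhat = da_h @ p["Wxh"].T
            drh = da_h @ p["Whh"].T
            dr = drh * h_dec
            dh_dec += drh * r

            da_z = dz * z * (1.0 - z)
            dxhat += da_z @ p["Wxz"].T
            dh_dec += da_z @ p["Whz"].T

            da_r = dr * r * (1.0 - r)
            dxhat += da_r @ p["Wxr"].T
            dh_dec += da_r @ p["Whr"].T

            grads["Wxh"] += xhat.T @ da_h
            grads["Whh"] += (r * h_dec).T @ da_h
            grads["Wmh"] += m.T @ da_h
            grads["bh"] += da_h.sum(axis=0)
            grads["Wxz"] += xhat.T @ da_z
            grads["Whz"] += h_dec.T @ da_z
            grads["Wmz"] += m.T @ da_z
            grads["bz"] += da_z.sum(axis=0)
            grads["Wxr"] += xhat.T @ da_r
            grads["Whr"] += h_dec.T @ da_r
            grads["Wmr"] += m.T @ da_r
            grads["br"] += da_r.sum(axis=0)

            dgh = dh_dec * h_prev
            dh = dh_dec * gh  # flows to h_{t-1}
            dgh_pre = -dgh * gh * gh_pos
            grads["Wgh"] += d.T @ dgh_pre
            grads["bgh"] += dgh_pre.sum(axis=0)

            dgx = (dxhat * (1.0 - m) * (xl - self.x_mean)).reshape(B, D)
            dgx_pre = -dgx * gx * gx_pos
            grads["wgx"] += (d * dgx_pre).sum(axis=0)
            grads["bgx"] += dgx_pre.sum(axis=0)
        return grads

    def predict_proba(self, inputs, batch_size: int = 512) -> np.ndarray:
        values, mask, delta, x_last = (np.asarray(a, dtype=float) for a in inputs)
        out = np.empty(len(values))
        for start in range(0, len(values), batch_size):
            sl = slice(start, start + batch_size)
            probs, _ = self.forward(
                (values[sl], mask[sl], delta[sl], x_last[sl]), train=False
            )
            out[sl] = probs
        return out

    def inputs_from(self, dataset):
        """The model's input tuple from a :class:`WindowDataset`."""
        return (dataset.X_raw, dataset.mask, dataset.delta, dataset.x_last)
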