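"""Dual-branch 1-D convolutional text classifier in pure numpy.

One branch: trainable embedding lookup -> [conv(channels, kernel) + ReLU
+ batch-norm] x n -> global max pool -> dropout.  The pooled branch
outputs are concatenated and passed through a dense layer (ReLU) and an
output layer of 11 units with sigmoid (independent multi-label
probabilities, the default) or softmax activation.  Forward, backward
and the Adam optimizer are implemented here directly; training is
single-threaded and fully seeded, so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5
_DTYPE = np.float32


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _softmax(x):
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sliding(x, k):
    # (B, L, C) -> (B, L-k+1, k, C)
    v = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    return np.ascontiguousarray(np.moveaxis(v, 3, 2))


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        corr1 = 1 - self.b1 ** self.t
        corr2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / corr1) / (
                np.sqrt(self.v[k] / corr2) + self.eps
            )


class DualBranchCNN:
    """CNN over token-id sequences; one or two weight-independent branches."""

    def __init__(
        self,
        embedding_init: np.ndarray,
        mode: str = "tagged",
        n_conv_layers: int = 3,
        channels: int = 128,
        kernel_width: int = 5,
        dropout_rate: float = 0.5,
        dense_width: int = 128,
        n_outputs: int = 11,
        output_activation: str = "sigmoid",
        seed: int = 0,
    ):
        if mode not in ("tagged", "not_tagged"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.n_branches = 2 if mode == "tagged" else 1
        self.n_conv = n_conv_layers
        self.channels = channels
        self.kernel = kernel_width
        self.dropout_rate = dropout_rate
        self.output_activation = output_activation
        self.n_outputs = n_outputs
        self.rng = np.random.default_rng(seed)
        self.embed_dim = embedding_init.shape[1]

        p: dict[str, np.ndarray] = {}
        for b in range(self.n_branches):
            p[f"E{b}"] = embedding_init.astype(_DTYPE).copy()
            c_in = self.embed_dim
            for l in range(self.n_conv):
                fan_in = c_in * kernel_width
                p[f"W{b}_{l}"] = self.rng.normal(
                    0, np.sqrt(2.0 / fan_in), (fan_in, channels)
                ).astype(_DTYPE)
                p[f"b{b}_{l}"] = np.zeros(channels, dtype=_DTYPE)
                p[f"g{b}_{l}"] = np.ones(channels, dtype=_DTYPE)  # batch-norm gain
                p[f"h{b}_{l}"] = np.zeros(channels, dtype=_DTYPE)  # batch-norm shift
                c_in = channels
        concat = channels * self.n_branches
        p["Wd"] = self.rng.normal(0, np.sqrt(2.0 / concat), (concat, dense_width)).astype(_DTYPE)
        p["bd"] = np.zeros(dense_width, dtype=_DTYPE)
        p["Wo"] = self.rng.normal(0, np.sqrt(2.0 / dense_width), (dense_width, n_outputs)).astype(_DTYPE)
        p["bo"] = np.zeros(n_outputs, dtype=_DTYPE)
        self.params = p
        # batch-norm running statistics (not optimized)
        self.running = {
            f"{s}{b}_{l}": (np.zeros(channels, dtype=_DTYPE) if s == "mu" else np.ones(channels, dtype=_DTYPE))
            for b in range(self.n_branches)
            for l in range(self.n_conv)
            for s in ("mu", "var")
        }
        self._momentum = 0.9

    # -- forward ----------------------------------------------------------

    def _branch_forward(self, b: int, ids: np.ndarray, train: bool, cache: dict):
        p = self.params
        x = p[f"E{b}"][ids]  # (B, L, D)
        cache[f"ids{b}"] = ids
        lengths = (ids != 0).sum(axis=1)  # id 0 is the pad token
        for l in range(self.n_conv):
            cols = _sliding(x, self.kernel)  # (B, L', k, C)
            B, Lp, k, C = cols.shape
            flat = cols.reshape(B * Lp, k * C)
            z = flat @ p[f"W{b}_{l}"] + p[f"b{b}_{l}"]
            r = np.maximum(z, 0.0)
            # windows overlapping real tokens; the constant padding tail is
            # excluded from batch statistics and from the max pool
            vmask = (
                np.arange(Lp)[None, :] < np.clip(lengths, 1, Lp)[:, None]
            ).reshape(-1)
            if train:
                rv = r[vmask]
                mu = rv.mean(axis=0)
                var = rv.var(axis=0)
                self.running[f"mu{b}_{l}"] = (
                    self._momentum * self.running[f"mu{b}_{l}"] + (1 - self._momentum) * mu
                )
                self.running[f"var{b}_{l}"] = (
                    self._momentum * self.running[f"var{b}_{l}"] + (1 - self._momentum) * var
                )
            else:
                mu = self.running[f"mu{b}_{l}"]
                var = self.running[f"var{b}_{l}"]
            inv = 1.0 / np.sqrt(var + _EPS)
            xhat = (r - mu) * inv
            y = p[f"g{b}_{l}"] * xhat + p[f"h{b}_{l}"]
            cache[f"conv{b}_{l}"] = (flat, z, xhat, inv, vmask, (B, Lp, k, C))
            x = y.reshape(B, Lp, -1)
        # max pool only over windows that overlap real tokens, so constant
        # activations on the padding tail cannot dominate the features
        Lp = x.shape[1]
        n_valid = np.clip(lengths, 1, Lp)
        valid = np.arange(Lp)[None, :] < n_valid[:, None]
        xm = np.where(valid[:, :, None], x, -np.inf)
        pooled = xm.max(axis=1)
        cache[f"argmax{b}"] = xm.argmax(axis=1)
        cache[f"poolshape{b}"] = x.shape
        if train and self.dropout_rate > 0:
            mask = (self.rng.random(pooled.shape) >= self.dropout_rate) / (
                1 - self.dropout_rate
            )
            pooled = pooled * mask
            cache[f"dropmask{b}"] = mask
        cache[f"pooled{b}"] = pooled
        return pooled

    def forward(self, inputs: tuple[np.ndarray, ...], train: bool = False):
        """inputs: (ids,) for not_tagged, (pos_ids, neg_ids) for tagged."""
        if len(inputs) != self.n_branches:
            raise ValueError(
                f"{self.mode} model expects {self.n_branches} input sequence(s)"
            )
        cache: dict = {}
        pooled = [self._branch_forward(b, inputs[b], train, cache) for b in range(self.n_branches)]
        h = np.concatenate(pooled, axis=1)
        cache["concat"] = h
        a = h @ self.params["Wd"] + self.params["bd"]
        d = np.maximum(a, 0.0)
        cache["dense_pre"], cache["dense"] = a, d
        logits = d @ self.params["Wo"] + self.params["bo"]
        cache["logits"] = logits
        probs = _softmax(logits) if self.output_activation == "softmax" else _sigmoid(logits)
        return probs, cache

    # -- loss and backward -------------------------------------------------

    def loss_and_grads(self, inputs, targets: np.ndarray):
        """Mean cross-entropy on a batch plus gradients for every parameter."""
        probs, cache = self.forward(inputs, train=True)
        B = targets.shape[0]
        if self.output_activation == "softmax":
            t = targets / np.maximum(targets.sum(axis=1, keepdims=True), 1e-12)
            loss = -np.mean(np.sum(t * np.log(probs + 1e-12), axis=1))
            dlogits = (probs - t) / B
        else:
            loss = -np.mean(
                targets * np.log(probs + 1e-12)
                + (1 - targets) * np.log(1 - probs + 1e-12)
            )
            dlogits = (probs - targets) / (B * self.n_outputs)

        p, g = self.params, {}
        g["Wo"] = cache["dense"].T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        dd = dlogits @ p["Wo"].T
        dd *= cache["dense_pre"] > 0
        g["Wd"] = cache["concat"].T @ dd
        g["bd"] = dd.sum(axis=0)
        dh = dd @ p["Wd"].T
        for b in range(self.n_branches):
            dpool = dh[:, b * self.channels : (b + 1) * self.channels]
            self._branch_backward(b, dpool, cache, g)
        return loss, g

    def _branch_backward(self, b: int, dpool: np.ndarray, cache: dict, g: dict):
        p = self.params
        if f"dropmask{b}" in cache:
            dpool = dpool * cache[f"dropmask{b}"]
        B, Lp, C = cache[f"poolshape{b}"]
        dx = np.zeros((B, Lp, C), dtype=_DTYPE)
        idx = cache[f"argmax{b}"]
        rows = np.arange(B)[:, None]
        cols_i = np.arange(C)[None, :]
        dx[rows, idx, cols_i] = dpool
        for l in range(self.n_conv - 1, -1, -1):
            flat, z, xhat, inv, vmask, (Bc, Lc, k, Cin) = cache[f"conv{b}_{l}"]
            dy = dx.reshape(Bc * Lc, -1)
            # batch-norm backward; statistics were estimated on the valid
            # (non-padding) windows, so the coupling terms divide by their
            # count and padding windows get the straight-through gradient
            Nv = max(1, int(vmask.sum()))
            g[f"g{b}_{l}"] = (dy * xhat).sum(axis=0)
            g[f"h{b}_{l}"] = dy.sum(axis=0)
            dxhat = dy * p[f"g{b}_{l}"]
            s1 = dxhat.sum(axis=0)
            s2 = (dxhat * xhat).sum(axis=0)
            dr = inv * dxhat
            dr[vmask] -= (inv / Nv) * (s1 + xhat[vmask] * s2)
            dz = dr * (z > 0)
            g[f"W{b}_{l}"] = flat.T @ dz
            g[f"b{b}_{l}"] = dz.sum(axis=0)
            dflat = dz @ p[f"W{b}_{l}"].T
            dcols = dflat.reshape(Bc, Lc, k, Cin)
            dxin = np.zeros((Bc, Lc + k - 1, Cin), dtype=_DTYPE)
            for i in range(k):
                dxin[:, i : i + Lc, :] += dcols[:, :, i, :]
            dx = dxin
        # embedding gradient (scatter-add over token positions)
        ids = cache[f"ids{b}"]
        gE = np.zeros_like(p[f"E{b}"])
        np.add.at(gE, ids.ravel(), dx.reshape(-1, dx.shape[2]))
        g[f"E{b}"] = gE

    # -- training utilities ------------------------------------------------

    def make_optimizer(self, lr: float) -> _Adam:
        return _Adam(self.params, lr)

    def state_copy(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "running": {k: v.copy() for k, v in self.running.items()},
        }

    def load_state(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k] = v.copy()
        for k, v in state["running"].items():
            self.running[k] = v.copy()

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def branch_parameter_count(self, b: int) -> int:
        prefixes = [f"E{b}"] + [
            f"{s}{b}_{l}" for l in range(self.n_conv) for s in ("W", "b", "g", "h")
        ]
        return sum(self.params[k].size for k in prefixes)
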