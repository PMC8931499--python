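"""Minimal feed-forward/attention building blocks with manual backprop.

Everything is plain numpy. Each layer keeps its parameters in ``self.params``
and writes parameter gradients into ``self.grads`` during ``backward`` (one
backward per forward; gradients are overwritten, not accumulated). Composite
layers recurse. The only optimizer provided is RMSprop, matching the training
recipe used throughout the package.
"""

from __future__ import annotations

import numpy as np


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


class Layer:
    """Base class: leaf layers override forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def children(self) -> list[tuple[str, "Layer"]]:
        return []

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.params.items()}
        for name, child in self.children():
            out.update(child.named_params(f"{prefix}{name}."))
        return out

    def param_grad_pairs(self):
        for k in self.params:
            yield self, k
        for _, child in self.children():
            yield from child.param_grad_pairs()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.params = {
            "W": glorot_uniform(rng, (d_in, d_out), d_in, d_out, dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads = {"W": x2.T @ dy2, "b": dy2.sum(axis=0)}
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class LayerNorm(Layer):
    """Row-wise standardization over the last axis + learned affine."""

    def __init__(self, d: int, dtype=np.float32, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(d, dtype=dtype), "beta": np.zeros(d, dtype=dtype)}

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        # exposed for tests of the pre-affine normalized statistics
        self.last_normalized = self._xhat
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        flat = dy.reshape(-1, dy.shape[-1])
        self.grads = {
            "gamma": (dy * xhat).reshape(-1, dy.shape[-1]).sum(axis=0),
            "beta": flat.sum(axis=0),
        }
        dxhat = dy * self.params["gamma"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention with h heads, d_k = d_v = d/h.

    ``scale="sqrt"`` divides scores by sqrt(d_k) (standard); ``"linear"``
    divides by d_k.
    """

    def __init__(self, d: int, h: int, rng: np.random.Generator, dtype=np.float32,
                 scale: str = "sqrt"):
        super().__init__()
        if d % h != 0:
            raise ValueError(f"n_heads={h} must divide d_model={d}")
        if scale not in ("sqrt", "linear"):
            raise ValueError("scale must be 'sqrt' or 'linear'")
        self.h, self.dk = h, d // h
        self.scale = (self.dk ** -0.5) if scale == "sqrt" else (1.0 / self.dk)
        self.params = {
            "Wq": glorot_uniform(rng, (h, d, self.dk), d, self.dk, dtype),
            "Wk": glorot_uniform(rng, (h, d, self.dk), d, self.dk, dtype),
            "Wv": glorot_uniform(rng, (h, d, self.dk), d, self.dk, dtype),
            "Wo": glorot_uniform(rng, (h * self.dk, d), h * self.dk, d, dtype),
            "bo": np.zeros(d, dtype=dtype),
        }

    def forward(self, x, train=False):
        # x: (B, n, d)
        B, n, d = x.shape
        X4 = x[:, None]                      # (B, 1, n, d)
        Q = X4 @ self.params["Wq"]           # (B, h, n, dk)
        K = X4 @ self.params["Wk"]
        V = X4 @ self.params["Wv"]
        S = (Q @ K.swapaxes(-1, -2)) * self.scale
        A = softmax(S, axis=-1)
        O = A @ V                            # (B, h, n, dk)
        concat = O.swapaxes(1, 2).reshape(B, n, self.h * self.dk)
        self._cache = (x, Q, K, V, A, concat)
        return concat @ self.params["Wo"] + self.params["bo"]

    def backward(self, dy):
        x, Q, K, V, A, concat = self._cache
        B, n, d = x.shape
        h, dk = self.h, self.dk
        dy2 = dy.reshape(-1, d)
        self.grads = {
            "Wo": concat.reshape(-1, h * dk).T @ dy2,
            "bo": dy2.sum(axis=0),
        }
        dconcat = dy @ self.params["Wo"].T                       # (B, n, h*dk)
        dO = dconcat.reshape(B, n, h, dk).swapaxes(1, 2)          # (B, h, n, dk)
        dA = dO @ V.swapaxes(-1, -2)
        dV = A.swapaxes(-1, -2) @ dO
        dS = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
        dS = dS * self.scale
        dQ = dS @ K
        dK = dS.swapaxes(-1, -2) @ Q
        X4T = x[:, None].swapaxes(-1, -2)                        # (B, 1, d, n)
        self.grads["Wq"] = (X4T @ dQ).sum(axis=0)
        self.grads["Wk"] = (X4T @ dK).sum(axis=0)
        self.grads["Wv"] = (X4T @ dV).sum(axis=0)
        dx = (
            (dQ @ self.params["Wq"].swapaxes(-1, -2)).sum(axis=1)
            + (dK @ self.params["Wk"].swapaxes(-1, -2)).sum(axis=1)
            + (dV @ self.params["Wv"].swapaxes(-1, -2)).sum(axis=1)
        )
        return dx


class PositionwiseDense(Layer):
    """Token-wise Dense -> ReLU -> Dense map back to model width.

    Serves both as the transformer feed-forward sublayer and (with width 128)
    as the attention replacement in the residual-dense baseline.
    """

    def __init__(self, d: int, width: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fc1 = Dense(d, width, rng, dtype)
        self.act = ReLU()
        self.fc2 = Dense(width, d, rng, dtype)

    def children(self):
        return [("fc1", self.fc1), ("fc2", self.fc2)]

    def forward(self, x, train=False):
        return self.fc2.forward(self.act.forward(self.fc1.forward(x, train), train), train)

    def backward(self, dy):
        return self.fc1.backward(self.act.backward(self.fc2.backward(dy)))


class ResidualNormBlock(Layer):
    """y = Norm(ReLU(sublayer(x) + x)) (literal form) or Norm(x + sublayer(x)).

    The literal form applies the rectifier to the residual sum before layer
    normalization; ``post_norm="standard"`` gives the conventional post-norm
    residual block for comparison.
    """

    def __init__(self, sublayer: Layer, d: int, dtype=np.float32, post_norm: str = "literal"):
        super().__init__()
        if post_norm not in ("literal", "standard"):
            raise ValueError("post_norm must be 'literal' or 'standard'")
        self.sub = sublayer
        self.norm = LayerNorm(d, dtype)
        self.post_norm = post_norm

    def children(self):
        return [("sub", self.sub), ("norm", self.norm)]

    def forward(self, x, train=False):
        z = self.sub.forward(x, train) + x
        if self.post_norm == "literal":
            self._mask = z > 0
            z = z * self._mask
        return self.norm.forward(z, train)

    def backward(self, dy):
        dz = self.norm.backward(dy)
        if self.post_norm == "literal":
            dz = dz * self._mask
        return self.sub.backward(dz) + dz


class EncoderLayer(Layer):
    """One stacked layer: self-attention block then feed-forward block.

    With ``attention=False`` the attention sublayer is replaced by a
    position-wise dense ReLU map (width ``replacement_units``) — the
    residual-dense baseline variant.
    """

    def __init__(self, d: int, h: int, ffn_width: int, rng: np.random.Generator,
                 dtype=np.float32, scale: str = "sqrt", post_norm: str = "literal",
                 attention: bool = True, replacement_units: int = 128):
        super().__init__()
        sub1: Layer
        if attention:
            sub1 = MultiHeadSelfAttention(d, h, rng, dtype, scale)
        else:
            sub1 = PositionwiseDense(d, replacement_units, rng, dtype)
        self.block1 = ResidualNormBlock(sub1, d, dtype, post_norm)
        self.block2 = ResidualNormBlock(PositionwiseDense(d, ffn_width, rng, dtype),
                                        d, dtype, post_norm)

    def children(self):
        return [("block1", self.block1), ("block2", self.block2)]

    def forward(self, x, train=False):
        return self.block2.forward(self.block1.forward(x, train), train)

    def backward(self, dy):
        return self.block1.backward(self.block2.backward(dy))


class RMSprop:
    """Root-mean-square propagation with the usual leaky average of g^2."""

    def __init__(self, pairs, learning_rate: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-8):
        self.pairs = list(pairs)
        self.lr, self.rho, self.eps = learning_rate, rho, eps
        self.cache = [np.zeros_like(layer.params[key]) for layer, key in self.pairs]

    def step(self) -> None:
        for (layer, key), c in zip(self.pairs, self.cache):
            g = layer.grads[key].astype(c.dtype)
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            layer.params[key] -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(
                layer.params[key].dtype
            )
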