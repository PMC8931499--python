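"""The stacked self-attention HFO classifier.

A segment of T samples is cut into ``T / frame_width`` consecutive frames
(tokens), linearly projected to ``d_model``, passed through ``n_layers``
identical blocks — multi-head self-attention and a position-wise feed-forward
sublayer, each wrapped as ``Norm(ReLU(sublayer(x) + x))`` — then flattened
into a dense head (128 ReLU -> 10 ReLU -> 1 sigmoid) that outputs the
probability that the segment contains an HFO. Training uses binary
cross-entropy, RMSprop, mini-batches of 32 and 10 epochs by default, with
dropout (rate 0.1) on the input during training.

No positional encoding is applied by default; the dense head sees the tokens
in order, so position information is not discarded. An optional sinusoidal
encoding is available behind ``positional_encoding=True``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .data import HFO, SegmentDataset
from . import nn
from .nn import (
    Dense,
    Dropout,
    EncoderLayer,
    Layer,
    ReLU,
    softmax,
)

_PROB_EPS = 1e-7


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    n_layers    : number of stacked identical layers N (0 degenerates to the
                  dense head alone).
    n_heads     : attention heads h; must divide d_model (d_k = d_v = d/h).
    d_model     : token embedding width d.
    frame_width : samples per token p; must divide the segment length T.
    ffn_width   : feed-forward sublayer width (default 4 * d_model).
    dense_units : widths of the classification head; must end in 1.
    attention_scale : "sqrt" (1/sqrt(d_k), default) or "linear" (1/d_k).
    post_norm   : "literal" Norm(ReLU(sub(x)+x)) or "standard" Norm(x+sub(x)).
    pool        : "flatten" (default) or "mean" over tokens before the head.
    """

    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 64
    frame_width: int = 20
    dropout_rate: float = 0.1
    dense_units: tuple[int, ...] = (128, 10, 1)
    ffn_width: int | None = None
    attention_scale: str = "sqrt"
    post_norm: str = "literal"
    positional_encoding: bool = False
    pool: str = "flatten"

    def __post_init__(self) -> None:
        if not (0 <= self.n_layers <= 40):
            raise ValueError("n_layers must be in [0, 40]")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"n_heads={self.n_heads} must divide d_model={self.d_model}"
            )
        if tuple(self.dense_units)[-1] != 1:
            raise ValueError("dense_units must end in 1 (single probability unit)")
        if self.pool not in ("flatten", "mean"):
            raise ValueError("pool must be 'flatten' or 'mean'")
        if self.ffn_width is None:
            self.ffn_width = 4 * self.d_model

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    d_v = d_k


@dataclass
class TrainConfig:
    optimizer: str = "rmsprop"
    batch_size: int = 32
    epochs: int = 10
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "rmsprop":
            raise ValueError("only rmsprop is supported")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


# ---------------------------------------------------------------------------
# functional building blocks (used directly by tests and docs)
# ---------------------------------------------------------------------------

def frame_tokens(x: np.ndarray, frame_width: int) -> np.ndarray:
    """Reshape a segment (or batch) into consecutive ``frame_width`` frames.

    Row i of the result holds samples ``[i*p, (i+1)*p)``; flattening the
    frame matrix recovers the segment exactly.
    """
    x = np.asarray(x)
    T = x.shape[-1]
    if T % frame_width != 0:
        valid = [w for w in range(1, min(T, 201)) if T % w == 0]
        raise ValueError(
            f"frame_width={frame_width} does not divide segment length {T}; "
            f"valid widths include {valid}"
        )
    return x.reshape(*x.shape[:-1], T // frame_width, frame_width)


def scaled_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                     scale: str = "sqrt") -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V with row-wise softmax.

    ``scale="linear"`` uses 1/d_k instead of 1/sqrt(d_k).
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share the key dimension")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must have the same number of rows")
    dk = Q.shape[-1]
    c = dk ** -0.5 if scale == "sqrt" else 1.0 / dk
    S = (Q @ K.swapaxes(-1, -2)) * c
    return softmax(S, axis=-1) @ V


def multi_head_attention(X: np.ndarray, Wq: np.ndarray, Wk: np.ndarray,
                         Wv: np.ndarray, Wo: np.ndarray, bo: np.ndarray | float = 0.0,
                         scale: str = "sqrt") -> np.ndarray:
    """Self-attention over h heads: Concat(head_1..head_h) W_O.

    ``Wq, Wk, Wv`` have shape (h, d, d_k); ``Wo`` has shape (h*d_v, d).
    Keys, values and queries all come from ``X`` (n x d).
    """
    X = np.asarray(X, dtype=float)
    h = Wq.shape[0]
    heads = [
        scaled_attention(X @ Wq[i], X @ Wk[i], X @ Wv[i], scale) for i in range(h)
    ]
    return np.concatenate(heads, axis=-1) @ Wo + bo


def dense_pool(s: np.ndarray, W1: np.ndarray, b1: np.ndarray,
               w: np.ndarray, b: float) -> float:
    """Scalar dense head o = w^T ReLU(W1 s + b1) + b."""
    hidden = np.maximum(W1 @ np.asarray(s, dtype=float) + b1, 0.0)
    return float(np.dot(w, hidden) + b)


def cross_entropy_loss(y: np.ndarray, p: np.ndarray, eps: float = _PROB_EPS) -> float:
    """Mean binary cross-entropy with probability clipping at ``eps``."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def sinusoidal_encoding(n_tokens: int, d_model: int, dtype=np.float64) -> np.ndarray:
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(dtype)


# ---------------------------------------------------------------------------
# the detector
# ---------------------------------------------------------------------------

class TransformerDetector:
    """Stacked self-attention segment classifier (sklearn-style interface).

    ``attention=False`` yields the residual-dense variant in which the
    attention sublayer of every block is replaced by a position-wise dense
    ReLU map of width ``replacement_units`` (the width of the first head
    layer), everything else unchanged.
    """

    def __init__(self, config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 attention: bool = True, replacement_units: int = 128,
                 dtype=np.float32):
        self.config = config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.attention = attention
        self.replacement_units = replacement_units
        self.dtype = dtype
        self._built_for: int | None = None
        self.history_: list[float] = []

    # -- construction ------------------------------------------------------
    def build(self, T: int, rng: np.random.Generator | None = None) -> "TransformerDetector":
        cfg = self.config
        if T % cfg.frame_width != 0:
            frame_tokens(np.empty(T), cfg.frame_width)  # raises with valid widths
        rng = rng or np.random.default_rng(self.train_config.seed)
        self._rng = rng
        n_tokens = T // cfg.frame_width
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self.input_proj = Dense(cfg.frame_width, cfg.d_model, rng, self.dtype)
        self.layers = [
            EncoderLayer(cfg.d_model, cfg.n_heads, cfg.ffn_width, rng, self.dtype,
                         cfg.attention_scale, cfg.post_norm, self.attention,
                         self.replacement_units)
            for _ in range(cfg.n_layers)
        ]
        head_in = cfg.d_model * (n_tokens if cfg.pool == "flatten" else 1)
        widths = [head_in, *cfg.dense_units]
        self.head: list[Layer] = []
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            self.head.append(Dense(a, b, rng, self.dtype))
            if i < len(cfg.dense_units) - 1:
                self.head.append(ReLU())
        self._pos = (
            sinusoidal_encoding(n_tokens, cfg.d_model, self.dtype)
            if cfg.positional_encoding else None
        )
        self._built_for = T
        return self

    def _modules(self) -> list[Layer]:
        return [self.input_proj, *self.layers, *self.head]

    def named_params(self) -> dict[str, np.ndarray]:
        out = self.input_proj.named_params("input_proj.")
        for i, layer in enumerate(self.layers):
            out.update(layer.named_params(f"layers.{i}."))
        for i, layer in enumerate(self.head):
            out.update(layer.named_params(f"head.{i}."))
        return out

    # -- forward / backward ------------------------------------------------
    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=self.dtype))
        if self._built_for is None:
            raise RuntimeError("model is not built/trained yet")
        if X.shape[1] != self._built_for:
            raise ValueError(
                f"segment length {X.shape[1]} != model input length {self._built_for}"
            )
        return X

    def _logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        cfg = self.config
        x = self.dropout.forward(X, train)
        tokens = frame_tokens(x, cfg.frame_width)
        z = self.input_proj.forward(tokens, train)
        if self._pos is not None:
            z = z + self._pos
        for layer in self.layers:
            z = layer.forward(z, train)
        self._pool_tokens = z.shape[1]
        if cfg.pool == "mean":
            z = z.mean(axis=1)
        else:
            z = z.reshape(z.shape[0], -1)
        for layer in self.head:
            z = layer.forward(z, train)
        return z[:, 0]

    def _backward(self, dlogit: np.ndarray) -> None:
        cfg = self.config
        dz: np.ndarray = dlogit[:, None]
        for layer in reversed(self.head):
            dz = layer.backward(dz)
        B = dz.shape[0]
        if cfg.pool == "mean":
            dz = np.repeat(dz[:, None, :], self._pool_tokens, axis=1) / self._pool_tokens
        else:
            dz = dz.reshape(B, self._pool_tokens, cfg.d_model)
        for layer in reversed(self.layers):
            dz = layer.backward(dz)
        dtokens = self.input_proj.backward(dz)
        self.dropout.backward(dtokens.reshape(B, -1))

    # -- training ------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "TransformerDetector":
        X = np.atleast_2d(np.asarray(X, dtype=self.dtype))
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        tcfg = self.train_config
        rng = np.random.default_rng(tcfg.seed)
        self.build(X.shape[1], rng)
        opt = nn.RMSprop(
            [p for m in self._modules() for p in m.param_grad_pairs()],
            learning_rate=tcfg.learning_rate,
        )
        n = X.shape[0]
        yb = (y == HFO).astype(self.dtype)
        self.history_ = []
        for _ in range(tcfg.epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, tcfg.batch_size):
                idx = order[start : start + tcfg.batch_size]
                logits = self._logits(X[idx], train=True)
                p = expit(logits.astype(np.float64))
                losses.append(cross_entropy_loss(yb[idx], p))
                weights.append(idx.size)
                dlogit = ((p - yb[idx]) / idx.size).astype(self.dtype)
                self._backward(dlogit)
                opt.step()
            self.history_.append(float(np.average(losses, weights=weights)))
        return self

    # -- inference -----------------------------------------------------------
    def predict_proba(self, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
        X = self._check_input(X)
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            out[sl] = expit(self._logits(X[sl], train=False).astype(np.float64))
        return np.clip(out, _PROB_EPS, 1.0 - _PROB_EPS)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def forward(self, segment: np.ndarray) -> float:
        """Probability that a single segment contains an HFO."""
        return float(self.predict_proba(np.atleast_2d(segment))[0])

    # -- persistence ---------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "weights.npz", **self.named_params())
        meta = {
            "config": asdict(self.config),
            "train_config": asdict(self.train_config),
            "attention": self.attention,
            "replacement_units": self.replacement_units,
            "input_length": self._built_for,
            "history": self.history_,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "TransformerDetector":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        meta["config"]["dense_units"] = tuple(meta["config"]["dense_units"])
        model = cls(ModelConfig(**meta["config"]), TrainConfig(**meta["train_config"]),
                    attention=meta["attention"],
                    replacement_units=meta["replacement_units"])
        model.build(meta["input_length"])
        params = model.named_params()
        with np.load(directory / "weights.npz") as z:
            for name, arr in params.items():
                arr[...] = z[name]
        model.history_ = list(meta.get("history", []))
        return model


def train(data: SegmentDataset, mcfg: ModelConfig | None = None,
          tcfg: TrainConfig | None = None, attention: bool = True):
    """Train a detector on a labeled dataset; returns (model, loss history)."""
    model = TransformerDetector(mcfg, tcfg, attention=attention)
    model.fit(data.X, data.y)
    return model, model.history_


def predict(model: TransformerDetector, segs, threshold: float = 0.5):
    """Classify segments; returns (labels, probabilities).

    ``segs`` may be a SegmentDataset, a matrix or a list of sample vectors.
    """
    if isinstance(segs, SegmentDataset):
        X = segs.X
    else:
        X = np.atleast_2d(np.asarray(segs, dtype=float))
    if X.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    probs = model.predict_proba(X)
    return (probs >= threshold).astype(int), probs
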