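"""Comparison classifiers: logistic regression, a stacked sparse autoencoder
(SSAE) detector, and the residual-dense variant of the attention model.

All detectors expose the same ``fit`` / ``predict_proba`` / ``predict``
interface as :class:`meghfo.model.TransformerDetector`, so the evaluation
machinery treats them interchangeably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .data import HFO
from .model import ModelConfig, TrainConfig, TransformerDetector, cross_entropy_loss


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

class LogisticDetector:
    """Logistic regression on flattened segments.

    features="envelope" (default) rectifies the (band-passed, normalized)
    samples first — the classical linear representation for HFO detection,
    where the discriminative information is the local amplitude of the
    band-limited signal rather than its sign, which carries an arbitrary
    oscillation phase. ``features="raw"`` fits the signed samples directly.

    ``C=None`` gives the pure maximum-likelihood fit (no penalty); the
    default keeps a mild ridge penalty because segments are far
    higher-dimensional than any realistic training set, which makes the
    classes perfectly separable and the unpenalized MLE divergent.
    """

    def __init__(self, features: str = "envelope", C: float | None = 1.0,
                 max_iter: int = 1000):
        if features not in ("envelope", "raw"):
            raise ValueError("features must be 'envelope' or 'raw'")
        self.features = features
        self.C = C
        self.max_iter = max_iter

    def _phi(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.abs(X) if self.features == "envelope" else X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticDetector":
        y = (np.asarray(y) == HFO).astype(int)
        if np.unique(y).size < 2:
            raise ValueError("training data must contain both classes")
        kwargs = dict(max_iter=self.max_iter)
        if self.C is None:
            kwargs["penalty"] = None
        else:
            kwargs["C"] = self.C
        self._lr = LogisticRegression(**kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # bounded-iteration convergence on separable data
            self._lr.fit(self._phi(X), y)
        return self

    @property
    def coef_(self) -> np.ndarray:
        return self._lr.coef_[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._lr.predict_proba(self._phi(X))[:, 1]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def train_lr(data, **kwargs) -> LogisticDetector:
    return LogisticDetector(**kwargs).fit(data.X, data.y)


def predict_lr(model: LogisticDetector, segs) -> np.ndarray:
    X = segs.X if hasattr(segs, "X") else np.atleast_2d(segs)
    return model.predict(X)


# ---------------------------------------------------------------------------
# residual-dense variant
# ---------------------------------------------------------------------------

@dataclass
class ResidualDenseConfig(ModelConfig):
    """Same depth semantics as the attention model; the attention sublayer of
    every block is swapped for a position-wise dense ReLU map whose width
    equals the first head layer (128 units)."""

    dense_replacement_units: int = 128


class DenseResidualDetector(TransformerDetector):
    def __init__(self, config: ResidualDenseConfig | ModelConfig | None = None,
                 train_config: TrainConfig | None = None, dtype=np.float32):
        config = config or ResidualDenseConfig()
        units = getattr(config, "dense_replacement_units", 128)
        super().__init__(config, train_config, attention=False,
                         replacement_units=units, dtype=dtype)


def build_residual_dense(cfg: ResidualDenseConfig | None = None,
                 tcfg: TrainConfig | None = None) -> DenseResidualDetector:
    return DenseResidualDetector(cfg, tcfg)


# ---------------------------------------------------------------------------
# stacked sparse autoencoder (SSAE)
# ---------------------------------------------------------------------------

@dataclass
class SSAEConfig:
    """Hyperparameters of the 4-layer SSAE detector.

    Three sigmoid hidden layers (default 30 units each) pre-trained greedily
    as sparse autoencoders — squared reconstruction error plus an L2 weight
    penalty and a KL-divergence sparsity penalty pulling the mean hidden
    activation toward ``sparsity_proportion`` — then fine-tuned end to end
    with a logistic output unit. Fine-tuning stops early when the validation
    loss is identical (within 1e-9) for ``early_stop_patience`` consecutive
    epochs.
    """

    hidden_sizes: tuple[int, ...] = (30, 30, 30)
    sparsity_proportion: float = 0.1
    l2_weight: float = 0.1
    sparsity_weight: float = 1.0
    learning_rate: float = 0.01
    early_stop_patience: int = 3
    pretrain_epochs: int = 15
    finetune_epochs: int = 30
    batch_size: int = 32
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be nonempty")
        if not (0 < self.sparsity_proportion < 1):
            raise ValueError("sparsity_proportion must be in (0, 1)")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be >= 0")


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """KL(rho || rho_hat) summed over hidden units; zero iff rho_hat == rho."""
    rho_hat = np.clip(rho_hat, 1e-10, 1 - 1e-10)
    return float(
        np.sum(rho * np.log(rho / rho_hat)
               + (1 - rho) * np.log((1 - rho) / (1 - rho_hat)))
    )


class SSAEDetector:
    """Greedy layer-wise pre-trained sparse autoencoder + logistic output."""

    def __init__(self, config: SSAEConfig | None = None):
        self.config = config or SSAEConfig()
        self.pretrain_losses_: list[list[float]] = []
        self.finetune_losses_: list[float] = []

    # one autoencoder layer: sigmoid encoder, linear decoder
    def _pretrain_layer(self, H: np.ndarray, n_hidden: int,
                        rng: np.random.Generator):
        cfg = self.config
        n, d = H.shape
        W = rng.normal(0, 1.0 / np.sqrt(d), (d, n_hidden))
        b = np.zeros(n_hidden)
        Wd = rng.normal(0, 1.0 / np.sqrt(n_hidden), (n_hidden, d))
        bd = np.zeros(d)
        losses = []
        for _ in range(cfg.pretrain_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                x = H[idx]
                a = expit(x @ W + b)
                rho_hat = a.mean(axis=0)
                xhat = a @ Wd + bd
                err = xhat - x
                m = idx.size
                loss = (
                    0.5 * np.mean(np.sum(err**2, axis=1))
                    + cfg.l2_weight * (np.sum(W**2) + np.sum(Wd**2))
                    + cfg.sparsity_weight
                    * kl_sparsity(cfg.sparsity_proportion, rho_hat)
                )
                epoch_loss += loss * m
                # gradients
                dxhat = err / m
                gWd = a.T @ dxhat + 2 * cfg.l2_weight * Wd
                gbd = dxhat.sum(axis=0)
                da = dxhat @ Wd.T
                rho_c = np.clip(rho_hat, 1e-10, 1 - 1e-10)
                dkl = (-cfg.sparsity_proportion / rho_c
                       + (1 - cfg.sparsity_proportion) / (1 - rho_c))
                da = da + cfg.sparsity_weight * dkl / m
                dz = da * a * (1 - a)
                gW = x.T @ dz + 2 * cfg.l2_weight * W
                gb = dz.sum(axis=0)
                W -= cfg.learning_rate * gW
                b -= cfg.learning_rate * gb
                Wd -= cfg.learning_rate * gWd
                bd -= cfg.learning_rate * gbd
            losses.append(epoch_loss / n)
        return W, b, losses

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SSAEDetector":
        cfg = self.config
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = (np.asarray(y) == HFO).astype(float)
        if np.unique(y).size < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(cfg.seed)
        n = X.shape[0]
        n_val = max(1, int(round(cfg.val_fraction * n)))
        if n - n_val < 2:
            raise ValueError("training set too small for a validation split")
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if np.unique(y[tr_idx]).size < 2:
            raise ValueError("degenerate validation split: one class left for training")
        Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

        # greedy layer-wise pre-training
        self.weights_: list[tuple[np.ndarray, np.ndarray]] = []
        self.pretrain_losses_ = []
        H = Xtr
        for n_hidden in cfg.hidden_sizes:
            W, b, losses = self._pretrain_layer(H, n_hidden, rng)
            self.weights_.append((W, b))
            self.pretrain_losses_.append(losses)
            H = expit(H @ W + b)
        d_top = cfg.hidden_sizes[-1]
        self._Wout = rng.normal(0, 1.0 / np.sqrt(d_top), d_top)
        self._bout = 0.0

        # supervised fine-tuning with equal-validation-loss early stopping
        self.finetune_losses_ = []
        patience, last_val = 0, None
        for _ in range(cfg.finetune_epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                self._finetune_step(Xtr[idx], ytr[idx])
            val_loss = cross_entropy_loss(yval, self._proba(Xval))
            self.finetune_losses_.append(val_loss)
            if last_val is not None and abs(val_loss - last_val) < 1e-9:
                patience += 1
                if patience >= cfg.early_stop_patience - 1:
                    break
            else:
                patience = 0
            last_val = val_loss
        return self

    def _hidden_pass(self, X: np.ndarray):
        acts = [X]
        for W, b in self.weights_:
            acts.append(expit(acts[-1] @ W + b))
        return acts

    def _proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self._hidden_pass(X)[-1] @ self._Wout + self._bout)

    def _finetune_step(self, x: np.ndarray, y: np.ndarray) -> None:
        cfg = self.config
        acts = self._hidden_pass(x)
        p = expit(acts[-1] @ self._Wout + self._bout)
        m = len(y)
        dlogit = (p - y) / m
        gW = acts[-1].T @ dlogit
        gb = dlogit.sum()
        da = np.outer(dlogit, self._Wout)
        self._Wout = self._Wout - cfg.learning_rate * gW
        self._bout = self._bout - cfg.learning_rate * gb
        for li in range(len(self.weights_) - 1, -1, -1):
            a = acts[li + 1]
            dz = da * a * (1 - a)
            W, b = self.weights_[li]
            gWl = acts[li].T @ dz
            gbl = dz.sum(axis=0)
            da = dz @ W.T
            self.weights_[li] = (W - cfg.learning_rate * gWl,
                                 b - cfg.learning_rate * gbl)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._proba(np.atleast_2d(np.asarray(X, dtype=float)))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def train_ssae(data, cfg: SSAEConfig | None = None) -> SSAEDetector:
    """Train the stacked-sparse-autoencoder detector on a labeled dataset."""
    return SSAEDetector(cfg).fit(data.X, data.y)


def select_ssae_config(data, sparsity_grid=(0.1, 0.2, 0.3, 0.4, 0.5),
                       l2_grid=(0.1, 0.2, 0.3, 0.4, 0.5), seed: int = 0,
                       **overrides) -> SSAEConfig:
    """Pick sparsity/L2 from the stated grids by validation accuracy.

    Selection uses a 20% holdout; returns the winning config (the selection
    protocol is a package choice).
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    n_val = max(1, int(round(0.2 * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    best, best_acc = None, -1.0
    for sp, l2 in product(sparsity_grid, l2_grid):
        cfg = SSAEConfig(sparsity_proportion=sp, l2_weight=l2, seed=seed, **overrides)
        model = SSAEDetector(cfg).fit(data.X[tr_idx], data.y[tr_idx])
        acc = float(np.mean(model.predict(data.X[val_idx]) == (data.y[val_idx] == HFO)))
        if acc > best_acc:
            best, best_acc = cfg, acc
    return best


# ---------------------------------------------------------------------------
# registry used by the evaluation machinery and the CLI
# ---------------------------------------------------------------------------

def make_model(name: str, seed: int = 0, **kwargs):
    """Build a fresh detector by name: 'lr', 'ssae', 'resdense' or 'attention'."""
    name = name.lower()
    if name == "lr":
        return LogisticDetector(**kwargs)
    if name == "ssae":
        cfg = kwargs.pop("config", None) or SSAEConfig(seed=seed, **kwargs)
        return SSAEDetector(cfg)
    if name in ("resdense", "attention"):
        mcfg = kwargs.pop("config", None)
        tcfg = kwargs.pop("train_config", None) or TrainConfig(seed=seed)
        tcfg.seed = seed
        if name == "resdense":
            return DenseResidualDetector(mcfg or ResidualDenseConfig(**kwargs), tcfg)
        return TransformerDetector(mcfg or ModelConfig(**kwargs), tcfg)
    raise ValueError(f"unknown model {name!r}; choose lr, ssae, resdense or attention")
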