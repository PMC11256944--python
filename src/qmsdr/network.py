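"""The drug response network: a gene-partitioned feed-forward regressor.

The model F maps a flattened feature tensor (genes x channels, gene-major)
to a scalar predicted AUDRC.  It has six hidden layers; layer 1 is
*partitioned by gene*: with ``x`` channels per gene, each gene's ``x``
inputs connect only to its own ``x`` layer-1 neurons (a block-diagonal
weight matrix), giving every gene a private embedding that is then
concatenated and passed to dense layers of 512, 512, 2048, 36 and 4
neurons.  Every layer applies the transfer function

    T(x) = Batchnorm(tanh(Linear(Dropout(x))))

and a final plain affine map takes the 4-neuron layer to the prediction.

Training minimises  O = MSE(y, y_hat) + lambda * ||W||^2  with mini-batch
gradient descent (batch 32) under AdamW — the weight penalty is realised
as decoupled weight decay on the weight matrices (biases and batch-norm
parameters are not decayed).  The learning rate starts at 0.014 and is
multiplied by 0.2 after 10 epochs without validation improvement; training
stops once validation MSE has not improved by at least 1e-4 for 20 epochs,
and the best-validation-epoch weights are restored.

Forward and backward passes are written directly in numpy; the backward
pass propagates exact analytic gradients through batch normalisation
(batch statistics in training mode, running statistics in inference),
tanh, the masked linear maps and dropout, for both parameters and inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigError, DimensionError, StateError, TrainingError

#: hidden-layer widths after the gene-partitioned layer, as used for the
#: full 702-gene clinical panel
DEFAULT_HIDDEN_SIZES = (512, 512, 2048, 36, 4)

#: a narrower stack suited to desk-scale synthetic cohorts (~200 genes)
COMPACT_HIDDEN_SIZES = (64, 64, 128, 36, 4)


def default_layer_sizes(
    n_genes: int, n_channels: int, hidden: Sequence[int] = DEFAULT_HIDDEN_SIZES
) -> tuple[int, ...]:
    return (n_genes * n_channels, *hidden)


@dataclass
class ModelConfig:
    """Architecture and optimisation settings for one drug model."""

    n_genes: int
    n_channels: int = 4
    layer_sizes: tuple[int, ...] | None = None
    dropout_p: float = 0.1
    weight_decay: float = 1e-4
    lr0: float = 0.014
    batch_size: int = 32
    lr_factor: float = 0.2
    lr_patience: int = 10
    early_stop_eps: float = 1e-4
    early_stop_patience: int = 20
    max_epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_sizes is None:
            self.layer_sizes = default_layer_sizes(self.n_genes, self.n_channels)
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if self.layer_sizes[0] != self.n_genes * self.n_channels:
            raise ConfigError(
                f"layer 1 size {self.layer_sizes[0]} != n_genes*x = "
                f"{self.n_genes * self.n_channels}"
            )
        if any(s < 1 for s in self.layer_sizes):
            raise ConfigError("all layer sizes must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigError("dropout_p must be in [0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch optimisation trace."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.val_mse)

    @property
    def stopped_epoch(self) -> int:
        return self.n_epochs - 1


class TransferLayer:
    """One application of T(x) = Batchnorm(tanh(Linear(Dropout(x)))).

    When ``block_shape=(n_genes, x)`` is given, the linear map is
    constrained block-diagonal by gene: the weights are stored as
    ``n_genes`` independent ``x by x`` blocks, so each gene's channels
    feed only its own neurons.  ``dense_weight()`` materialises the
    equivalent full (block-diagonal) matrix for inspection.  Batch
    normalisation keeps exponential running statistics (momentum 0.1)
    for inference.
    """

    def __init__(
        self,
        fan_in: int,
        fan_out: int,
        rng: np.random.Generator,
        dropout_p: float = 0.0,
        block_shape: tuple[int, int] | None = None,
        bn_eps: float = 1e-5,
        bn_momentum: float = 0.1,
    ):
        self.fan_in = fan_in
        self.fan_out = fan_out
        self.block_shape = block_shape
        if block_shape is not None:
            n_genes, x = block_shape
            if fan_in != n_genes * x or fan_out != n_genes * x:
                raise ConfigError("block layer must map n_genes*x -> n_genes*x")
            k = 1.0 / np.sqrt(x)  # effective fan-in per neuron is x
            self.W = rng.uniform(-k, k, size=(n_genes, x, x))
        else:
            k = 1.0 / np.sqrt(fan_in)
            self.W = rng.uniform(-k, k, size=(fan_in, fan_out))
        self.b = rng.uniform(-k, k, size=fan_out)
        self.gamma = np.ones(fan_out)
        self.beta = np.zeros(fan_out)
        self.running_mean = np.zeros(fan_out)
        self.running_var = np.ones(fan_out)
        self.dropout_p = dropout_p
        self.bn_eps = bn_eps
        self.bn_momentum = bn_momentum

    def dense_weight(self) -> np.ndarray:
        """The full (fan_in, fan_out) matrix; block-diagonal when partitioned."""
        if self.block_shape is None:
            return self.W
        n_genes, x = self.block_shape
        dense = np.zeros((self.fan_in, self.fan_out))
        for g in range(n_genes):
            dense[g * x : (g + 1) * x, g * x : (g + 1) * x] = self.W[g]
        return dense

    def _linear(self, x: np.ndarray) -> np.ndarray:
        if self.block_shape is None:
            return x @ self.W + self.b
        n_genes, c = self.block_shape
        xr = x.reshape(len(x), n_genes, c)
        z = np.einsum("ngc,gcd->ngd", xr, self.W)
        return z.reshape(len(x), -1) + self.b

    def forward(
        self,
        x: np.ndarray,
        training: bool,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        if x.shape[1] != self.fan_in:
            raise DimensionError(
                f"layer expects fan-in {self.fan_in}, got {x.shape[1]}"
            )
        cache: dict = {"training": training}
        if training and self.dropout_p > 0.0:
            if rng is None:
                raise StateError("training-mode dropout requires an RNG")
            keep = rng.random(x.shape) >= self.dropout_p
            scale = keep / (1.0 - self.dropout_p)
            x = x * scale
            cache["drop_scale"] = scale
        z = self._linear(x)
        t = np.tanh(z)
        if training:
            mu = t.mean(axis=0)
            var = t.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.bn_eps)
            xhat = (t - mu) * inv_std
            n = t.shape[0]
            unbiased = var * n / max(n - 1, 1)
            m = self.bn_momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.bn_eps)
            xhat = (t - self.running_mean) * inv_std
        out = self.gamma * xhat + self.beta
        cache.update(x_drop=x, t=t, xhat=xhat, inv_std=inv_std)
        return out, cache

    def backward(
        self, grad_out: np.ndarray, cache: dict
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        xhat, t, inv_std = cache["xhat"], cache["t"], cache["inv_std"]
        d_gamma = (grad_out * xhat).sum(axis=0)
        d_beta = grad_out.sum(axis=0)
        d_xhat = grad_out * self.gamma
        if cache["training"]:
            n = t.shape[0]
            d_t = (
                inv_std
                / n
                * (
                    n * d_xhat
                    - d_xhat.sum(axis=0)
                    - xhat * (d_xhat * xhat).sum(axis=0)
                )
            )
        else:
            d_t = d_xhat * inv_std
        d_z = d_t * (1.0 - t**2)
        x_drop = cache["x_drop"]
        if self.block_shape is None:
            d_W = x_drop.T @ d_z
            d_x = d_z @ self.W.T
        else:
            n_genes, c = self.block_shape
            xr = x_drop.reshape(len(x_drop), n_genes, c)
            dzr = d_z.reshape(len(d_z), n_genes, c)
            d_W = np.einsum("ngc,ngd->gcd", xr, dzr)
            d_x = np.einsum("ngd,gcd->ngc", dzr, self.W).reshape(len(d_z), -1)
        d_b = d_z.sum(axis=0)
        if "drop_scale" in cache:
            d_x = d_x * cache["drop_scale"]
        grads = {"W": d_W, "b": d_b, "gamma": d_gamma, "beta": d_beta}
        return grads, d_x


class ResponseNetwork:
    """The six-layer gene-partitioned regressor with a linear output head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sizes = config.layer_sizes
        self.layers: list[TransferLayer] = []
        fan_in = config.n_genes * config.n_channels
        for i, fan_out in enumerate(sizes):
            block = (config.n_genes, config.n_channels) if i == 0 else None
            self.layers.append(
                TransferLayer(
                    fan_in, fan_out, rng, dropout_p=config.dropout_p,
                    block_shape=block,
                )
            )
            fan_in = fan_out
        k = 1.0 / np.sqrt(fan_in)
        self.head_W = rng.uniform(-k, k, size=(fan_in, 1))
        self.head_b = rng.uniform(-k, k, size=1)
        self._train_mode = False

    # -- mode ---------------------------------------------------------------

    def train(self) -> "ResponseNetwork":
        self._train_mode = True
        return self

    def eval(self) -> "ResponseNetwork":
        self._train_mode = False
        return self

    @property
    def train_mode(self) -> bool:
        return self._train_mode

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            params[f"layer{i}.W"] = layer.W
            params[f"layer{i}.b"] = layer.b
            params[f"layer{i}.gamma"] = layer.gamma
            params[f"layer{i}.beta"] = layer.beta
        params["head.W"] = self.head_W
        params["head.b"] = self.head_b
        return params

    def weight_keys(self) -> set[str]:
        """Parameter names subject to the l2 penalty / weight decay."""
        return {k for k in self.parameters() if k.endswith(".W")}

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())

    def snapshot(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        for i, layer in enumerate(self.layers):
            state[f"layer{i}.running_mean"] = layer.running_mean.copy()
            state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def restore(self, state: Mapping[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in params.items():
            v[...] = state[k]
        for i, layer in enumerate(self.layers):
            layer.running_mean = state[f"layer{i}.running_mean"].copy()
            layer.running_var = state[f"layer{i}.running_var"].copy()

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list[dict]]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if X.shape[1] != self.config.n_genes * self.config.n_channels:
            raise DimensionError(
                f"input has {X.shape[1]} features, model expects "
                f"{self.config.n_genes * self.config.n_channels}"
            )
        caches = []
        h = X
        for layer in self.layers:
            h, cache = layer.forward(h, training=training, rng=rng)
            caches.append(cache)
        yhat = (h @ self.head_W + self.head_b).ravel()
        caches.append({"h_last": h})
        return yhat, caches

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic inference-mode predictions (one scalar per sample)."""
        yhat, _ = self.forward(X, training=False)
        return yhat

    def backward(
        self, caches: list[dict], d_yhat: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backpropagate d(objective)/d(yhat) to all parameters and the input."""
        head_cache = caches[-1]
        d_yhat = d_yhat.reshape(-1, 1)
        grads: dict[str, np.ndarray] = {
            "head.W": head_cache["h_last"].T @ d_yhat,
            "head.b": d_yhat.sum(axis=0),
        }
        d_h = d_yhat @ self.head_W.T
        for i in range(len(self.layers) - 1, -1, -1):
            layer_grads, d_h = self.layers[i].backward(d_h, caches[i])
            for k, v in layer_grads.items():
                grads[f"layer{i}.{k}"] = v
        return grads, d_h

    # -- objective ----------------------------------------------------------

    def penalty(self) -> float:
        wd = self.config.weight_decay
        return wd * sum(float((p**2).sum()) for k, p in self.parameters().items()
                        if k in self.weight_keys())

    def objective_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        training: bool = True,
        rng: np.random.Generator | None = None,
        include_penalty: bool = True,
    ) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
        """Evaluate O = MSE + lambda*||W||^2 and its exact gradients.

        Returns (objective, parameter gradients, input gradients).  With
        ``include_penalty=False`` only the MSE term is differentiated
        (the penalty is then handled by decoupled weight decay in the
        optimiser).
        """
        y = np.asarray(y, dtype=float).ravel()
        yhat, caches = self.forward(X, training=training, rng=rng)
        resid = yhat - y
        mse = float((resid**2).mean())
        obj = mse
        d_yhat = 2.0 * resid / resid.size
        grads, d_X = self.backward(caches, d_yhat)
        if include_penalty:
            obj += self.penalty()
            wd = self.config.weight_decay
            params = self.parameters()
            for k in self.weight_keys():
                grads[k] = grads[k] + 2.0 * wd * params[k]
        return obj, grads, d_X

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        """d(yhat)/d(input) per sample, inference mode; shape matches X."""
        orig_shape = np.asarray(X).shape
        yhat, caches = self.forward(X, training=False)
        _, d_X = self.backward(caches, np.ones_like(yhat))
        return d_X.reshape(orig_shape)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        arrays = self.snapshot()
        arrays["__config__"] = np.array(
            json.dumps(asdict(self.config)), dtype=object
        )
        if metadata:
            arrays["__metadata__"] = np.array(json.dumps(metadata), dtype=object)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["ResponseNetwork", dict]:
        with np.load(path, allow_pickle=True) as z:
            cfg = json.loads(str(z["__config__"]))
            cfg["layer_sizes"] = tuple(cfg["layer_sizes"])
            model = cls(ModelConfig(**cfg))
            state = {k: z[k] for k in z.files if not k.startswith("__")}
            model.restore(state)
            meta = (
                json.loads(str(z["__metadata__"])) if "__metadata__" in z.files else {}
            )
        return model, meta


def init_model(config: ModelConfig) -> ResponseNetwork:
    """Instantiate a freshly initialised network from a config."""
    return ResponseNetwork(config)


class AdamW:
    """Decoupled-weight-decay Adam over a named parameter dict.

    Weight decay is applied multiplicatively to the parameters named in
    ``decay_keys`` (the weight matrices), outside the adaptive gradient
    update — the standard decoupled formulation.
    """

    def __init__(
        self,
        params: Mapping[str, np.ndarray],
        lr: float,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        decay_keys: set[str] | None = None,
    ):
        self.params = dict(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.decay_keys = decay_keys if decay_keys is not None else set()
        self.m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.t = 0

    def step(self, grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            if k in self.decay_keys and self.weight_decay > 0.0:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class PlateauScheduler:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without the monitored loss improving by at least ``eps``."""

    def __init__(self, lr0: float, factor: float, patience: int, eps: float):
        self.lr = lr0
        self.factor = factor
        self.patience = patience
        self.eps = eps
        self.best = np.inf
        self.wait = 0

    def update(self, loss: float) -> float:
        if self.best - loss >= self.eps:
            self.best = loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr *= self.factor
                self.wait = 0
        return self.lr


class EarlyStopper:
    """Signal a stop after ``patience`` epochs without >= ``eps`` improvement."""

    def __init__(self, patience: int, eps: float):
        self.patience = patience
        self.eps = eps
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0
        self._epoch = -1

    def update(self, loss: float) -> bool:
        self._epoch += 1
        if self.best - loss >= self.eps:
            self.best = loss
            self.best_epoch = self._epoch
            self.wait = 0
        else:
            self.wait += 1
        return self.wait >= self.patience


def train(
    model: ResponseNetwork,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> tuple[ResponseNetwork, TrainHistory]:
    """Fit the network with AdamW, plateau scheduling and early stopping.

    Returns the model restored to its best-validation-epoch weights,
    along with the per-epoch history.  Train/validation sample sets must
    be disjoint (enforced upstream by the CV harness).
    """
    cfg = model.config
    X_train = np.asarray(X_train, dtype=float).reshape(len(X_train), -1)
    X_val = np.asarray(X_val, dtype=float).reshape(len(X_val), -1)
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    n = len(X_train)
    if n < 1 or len(X_val) < 1:
        raise TrainingError("train and validation sets must be non-empty")

    # start from the baseline predictor: the output bias opens at the
    # training-set mean response, so optimisation spends its budget on
    # structure rather than on walking the bias to the response scale
    model.head_b[:] = y_train.mean()

    rng = np.random.default_rng([cfg.seed, 1])
    opt = AdamW(
        model.parameters(),
        lr=cfg.lr0,
        weight_decay=cfg.weight_decay,
        decay_keys=model.weight_keys(),
    )
    sched = PlateauScheduler(cfg.lr0, cfg.lr_factor, cfg.lr_patience, cfg.early_stop_eps)
    stopper = EarlyStopper(cfg.early_stop_patience, cfg.early_stop_eps)
    history = TrainHistory()
    best_state = model.snapshot()

    model.train()
    for epoch in range(cfg.max_epochs):
        history.learning_rates.append(opt.lr)
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 samples
            obj, grads, _ = model.objective_and_grads(
                X_train[idx], y_train[idx], training=True, rng=rng,
                include_penalty=False,
            )
            if not np.isfinite(obj):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.step(grads)
            epoch_loss += obj * len(idx)
        history.train_mse.append(epoch_loss / n)

        model.eval()
        val_mse = float(((model.predict(X_val) - y_val) ** 2).mean())
        model.train()
        if not np.isfinite(val_mse):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history.val_mse.append(val_mse)

        improved = stopper.best - val_mse >= cfg.early_stop_eps
        stop = stopper.update(val_mse)
        if improved:
            best_state = model.snapshot()
            history.best_epoch = epoch
        opt.lr = sched.update(val_mse)
        if stop:
            history.stop_reason = "early_stop"
            break
    else:
        history.stop_reason = "max_epochs"

    model.restore(best_state)
    model.eval()
    return model, history
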