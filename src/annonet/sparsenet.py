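"""Annotation-defined sparse layers and a deterministic CPU training loop.

A :class:`SparseLayer` keeps one learnable weight per connectivity link and
one bias per output node; non-links are structurally absent, so the parameter
count of a network equals the number of biological relations it encodes plus
its biases. Each layer computes

    Y = activation(sum_i x_i * w_i + B)

restricted to the annotated links, implemented as sparse matrix
multiplication. Every layer is preceded by batch normalisation without
learnable scale or shift, so inputs to each layer have (approximately) zero
mean and unit variance and learned weights are directly comparable — the
basis of the interpretation module.

Training uses weighted binary cross-entropy (classification) or mean squared
error (regression) plus an L1 penalty on weights, minimised by Adam or
Adadelta with early stopping on the validation loss. Forward and backward
passes are written out explicitly over numpy/scipy.sparse; tests verify them
against masked-dense and finite-difference oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from .annotations import AnnotationError, ConnectivityMatrix, validate_stack

logger = logging.getLogger(__name__)

EPS_CLIP = 1e-7  # probability clipping before log


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACT = {
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "sigmoid": (_sigmoid, lambda z, a: a * (1.0 - a)),
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
}


# ---------------------------------------------------------------------------
# batch normalisation without scale/shift
# ---------------------------------------------------------------------------

class BatchNorm:
    """Per-feature (x - mean)/sqrt(var + eps) with no learnable affine terms.

    Training mode uses batch (population) statistics and updates running
    moments with momentum; inference mode uses the running moments. Zero
    batch variance is absorbed by ``eps`` and never produces NaN.
    """

    def __init__(self, n_features: int, eps: float = 1e-3, momentum: float = 0.99):
        self.n = n_features
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x: np.ndarray, training: bool):
        if training:
            if x.shape[0] < 2:
                raise ValueError("batch normalisation needs batch size >= 2 in training")
            mean = x.mean(axis=0)
            var = x.var(axis=0)  # population variance
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        return xhat, (xhat, inv_std)

    @staticmethod
    def backward(dy: np.ndarray, cache) -> np.ndarray:
        xhat, inv_std = cache
        n = dy.shape[0]
        return (inv_std / n) * (
            n * dy - dy.sum(axis=0) - xhat * (dy * xhat).sum(axis=0)
        )


def batchnorm_plain(x: np.ndarray, training: bool = True,
                    bn: BatchNorm | None = None) -> np.ndarray:
    """Functional batch normalisation without scaling and centering terms."""
    if bn is None:
        bn = BatchNorm(x.shape[1])
    out, _ = bn.forward(x, training)
    return out


# ---------------------------------------------------------------------------
# sparse layer
# ---------------------------------------------------------------------------

class SparseLayer:
    """One learnable weight per link of a connectivity matrix, one bias per output."""

    def __init__(self, cm: ConnectivityMatrix, activation: str = "tanh"):
        if activation not in _ACT:
            raise ValueError(f"unknown activation {activation!r}")
        self.cm = cm
        self.activation = activation
        self.rows = cm.row
        self.cols = cm.col
        self.n_in = cm.n_inputs
        self.n_out = cm.n_outputs
        # CSR structure is fixed; map canonical link order -> CSR data slots
        template = sp.csr_matrix(
            (np.arange(1, cm.n_links + 1, dtype=np.int64), (self.rows, self.cols)),
            shape=(self.n_in, self.n_out),
        )
        self._indices = template.indices
        self._indptr = template.indptr
        self._perm = template.data - 1  # csr slot k holds link _perm[k]
        self.w = np.zeros(cm.n_links)
        self.b = np.zeros(self.n_out)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def initialize(self, rng: np.random.Generator) -> None:
        """Uniform init in +-sqrt(6/(fan_in+1)) per output node's fan-in; zero bias."""
        fan_in = np.bincount(self.cols, minlength=self.n_out).astype(float)
        limit = np.sqrt(6.0 / (fan_in[self.cols] + 1.0))
        self.w = rng.uniform(-1.0, 1.0, self.w.size) * limit
        self.b = np.zeros(self.n_out)

    def _weight_matrix(self) -> sp.csr_matrix:
        return sp.csr_matrix(
            (self.w[self._perm], self._indices, self._indptr),
            shape=(self.n_in, self.n_out),
        )

    def forward(self, x: np.ndarray, capture: bool = False):
        """activation(x @ W + b); with ``capture`` also return a backward cache."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValueError(
                f"input width {x.shape[-1] if x.ndim else '?'} != {self.n_in} layer inputs"
            )
        W = self._weight_matrix()
        z = np.asarray(x @ W) + self.b
        f, _ = _ACT[self.activation]
        a = f(z)
        if capture:
            return a, (x, z, a, W)
        return a

    def backward(self, dy: np.ndarray, cache):
        """Gradients of a scalar loss given dL/dY. Returns (dx, dw, db)."""
        x, z, a, W = cache
        _, df = _ACT[self.activation]
        dz = dy * df(z, a)
        db = dz.sum(axis=0)
        dw = np.einsum("bi,bi->i", x[:, self.rows], dz[:, self.cols])
        dx = np.asarray(dz @ W.T)
        return dx, dw, db


def sparse_forward(layer: SparseLayer, x: np.ndarray) -> np.ndarray:
    """Forward pass of a single sparse layer (inference semantics)."""
    return layer.forward(x)


def all_to_one(input_names: Sequence[str], output_name: str = "output",
               level_label: str = "->output") -> ConnectivityMatrix:
    """Connectivity connecting every input node to a single output node."""
    n = len(input_names)
    return ConnectivityMatrix(
        tuple(input_names), (output_name,),
        np.arange(n, dtype=np.int64), np.zeros(n, dtype=np.int64), level_label,
    )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Stacked sparse layers, each preceded by plain batch normalisation."""

    layers: list
    task: str = "classification"
    batchnorm_before_each_layer: bool = True
    l1_penalty: float = 0.0
    bns: list = field(default_factory=list)

    def __post_init__(self):
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if a.n_out != b.n_in:
                raise AnnotationError("consecutive layer shapes do not chain")
        if self.layers[-1].n_out != 1:
            raise AnnotationError("final layer must have exactly one output node")
        if not self.bns:
            self.bns = [BatchNorm(layer.n_in) for layer in self.layers]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def initialize(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.initialize(rng)
        self.bns = [BatchNorm(layer.n_in) for layer in self.layers]

    def forward(self, x: np.ndarray, training: bool = False, capture: bool = False):
        caches = []
        layer_inputs = []
        for layer, bn in zip(self.layers, self.bns):
            if self.batchnorm_before_each_layer:
                x, bn_cache = bn.forward(x, training)
            else:
                bn_cache = None
            layer_inputs.append(x)
            if capture:
                x, lcache = layer.forward(x, capture=True)
                caches.append((bn_cache, lcache))
            else:
                x = layer.forward(x)
        out = x[:, 0]
        if capture:
            return out, caches, layer_inputs
        return out

    def backward(self, dz_out: np.ndarray, caches):
        """Backpropagate dL/d(pre-activation of output) through all layers.

        The output layer's activation derivative is assumed to be already
        folded into ``dz_out`` (sigmoid+BCE and linear+MSE both simplify to
        prediction minus target). Returns per-layer (dw, db) gradients.
        """
        grads = [None] * len(self.layers)
        dy = dz_out[:, None]
        for k in range(len(self.layers) - 1, -1, -1):
            bn_cache, lcache = caches[k]
            layer = self.layers[k]
            if k == len(self.layers) - 1:
                # dz already includes the output activation derivative
                x, z, a, W = lcache
                db = dy.sum(axis=0)
                dw = np.einsum("bi,bi->i", x[:, layer.rows], dy[:, layer.cols])
                dx = np.asarray(dy @ W.T)
            else:
                dx, dw, db = layer.backward(dy, lcache)
            grads[k] = (dw, db)
            if bn_cache is not None:
                dx = BatchNorm.backward(dx, bn_cache)
            dy = dx
        return grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode prediction (running batch-norm moments)."""
        return self.forward(np.asarray(x, dtype=float), training=False)

    def get_state(self):
        return (
            [(layer.w.copy(), layer.b.copy()) for layer in self.layers],
            [(bn.running_mean.copy(), bn.running_var.copy()) for bn in self.bns],
        )

    def set_state(self, state):
        params, moments = state
        for layer, (w, b) in zip(self.layers, params):
            layer.w = w.copy()
            layer.b = b.copy()
        for bn, (m, v) in zip(self.bns, moments):
            bn.running_mean = m.copy()
            bn.running_var = v.copy()


def assemble(
    matrices: Sequence[ConnectivityMatrix],
    task: str = "classification",
    hidden_activation: str | None = None,
) -> NetworkSpec:
    """Stack connectivity matrices into a network specification.

    One sparse layer per matrix, plus a final all-to-one layer whenever the
    last matrix does not already end in a single node. Classification uses
    tanh hidden activations and a sigmoid output; regression uses ReLU hidden
    activations and a linear output.
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    report = validate_stack(matrices)  # raises on chaining violations
    if report.warnings:
        for w in report.warnings:
            logger.warning("assemble: %s", w)
    if hidden_activation is None:
        hidden_activation = "tanh" if task == "classification" else "relu"
    out_act = "sigmoid" if task == "classification" else "linear"
    cms = list(matrices)
    if cms[-1].n_outputs > 1:
        cms.append(all_to_one(cms[-1].output_names))
    layers = []
    for k, cm in enumerate(cms):
        act = out_act if k == len(cms) - 1 else hidden_activation
        layers.append(SparseLayer(cm, act))
    return NetworkSpec(layers=layers, task=task)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def class_weights_from_labels(y: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency weights normalised to mean one: w1=n/(2*n_cases)."""
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("cannot derive class weights from a single-class dataset")
    n = n0 + n1
    return n / (2.0 * n0), n / (2.0 * n1)


def weighted_bce(y: np.ndarray, p: np.ndarray,
                 class_weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Mean of -[w1*y*log(p) + w0*(1-y)*log(1-p)], with p clipped at 1e-7."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), EPS_CLIP, 1.0 - EPS_CLIP)
    w0, w1 = class_weights
    return float(-np.mean(w1 * y * np.log(p) + w0 * (1.0 - y) * np.log(1.0 - p)))


def mse(y: np.ndarray, p: np.ndarray) -> float:
    return float(np.mean((np.asarray(p, float) - np.asarray(y, float)) ** 2))


def l1_term(spec: NetworkSpec) -> float:
    """penalty * total absolute weight over all layers; biases excluded."""
    if spec.l1_penalty == 0:
        return 0.0
    return float(spec.l1_penalty * sum(np.abs(layer.w).sum() for layer in spec.layers))


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list = []
        self.v: list = []

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class Adadelta:
    def __init__(self, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.eg: list = []
        self.ed: list = []

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self.eg:
            self.eg = [np.zeros_like(p) for p in params]
            self.ed = [np.zeros_like(p) for p in params]
        for p, g, eg, ed in zip(params, grads, self.eg, self.ed):
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = np.sqrt((ed + self.eps) / (eg + self.eps)) * g
            ed *= self.rho
            ed += (1 - self.rho) * dx * dx
            p -= self.lr * dx


_OPTIMIZERS = {"adam": Adam, "adadelta": Adadelta}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    l1_penalty: float = 0.0
    batch_size: int = 64
    patience_epochs: int = 10
    max_epochs: int = 500
    class_weights: tuple[float, float] | None = None  # None -> derive from labels
    seed: int = 0

    def __post_init__(self):
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if (self.learning_rate <= 0 or self.batch_size < 2
                or self.patience_epochs < 1 or self.max_epochs < 1
                or self.l1_penalty < 0):
            raise ValueError("invalid training configuration")


class EarlyStopper:
    """Stop after ``patience`` epochs without validation-loss improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0
        self.stop = False

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch; returns True if this epoch is the new best."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.wait = 0
            return True
        self.wait += 1
        if self.wait >= self.patience:
            self.stop = True
        return False


@dataclass
class TrainResult:
    net: NetworkSpec
    history: pd.DataFrame
    best_epoch: int
    stopped_epoch: int


def _safe_auc(y: np.ndarray, p: np.ndarray) -> float:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, p))


def train(
    net: NetworkSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
) -> TrainResult:
    """Mini-batch training with early stopping on the validation loss.

    The monitored validation loss is the full objective (data loss plus the
    L1 penalty), mirroring common deep-learning framework semantics.
    Fully reproducible given ``cfg.seed`` (a single generator drives weight
    initialisation and batch shuffling). Weights from the epoch with the
    lowest validation loss are restored before returning. Batches with fewer
    than two samples are skipped (batch normalisation needs a moment
    estimate). Raises :class:`TrainingDiverged` on non-finite loss.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    net.initialize(rng)
    net.l1_penalty = cfg.l1_penalty

    classification = net.task == "classification"
    if classification:
        cw = cfg.class_weights or class_weights_from_labels(y_train)
    else:
        cw = (1.0, 1.0)

    opt = _OPTIMIZERS[cfg.optimizer](lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.patience_epochs)
    best_state = net.get_state()
    rows = []
    n = X_train.shape[0]
    stopped_epoch = -1
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue
            xb, yb = X_train[idx], y_train[idx]
            p, caches, _ = net.forward(xb, training=True, capture=True)
            if classification:
                pc = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
                loss = weighted_bce(yb, pc, cw)
                w0, w1 = cw
                sw = np.where(yb == 1, w1, w0)
                dz = sw * (pc - yb) / idx.size
            else:
                loss = mse(yb, p)
                dz = 2.0 * (p - yb) / idx.size
            loss += l1_term(net)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} "
                    f"(optimizer={cfg.optimizer}, lr={cfg.learning_rate})"
                )
            grads = net.backward(dz, caches)
            params, gs = [], []
            for layer, (dw, db) in zip(net.layers, grads):
                if cfg.l1_penalty:
                    dw = dw + cfg.l1_penalty * np.sign(layer.w)
                params.extend([layer.w, layer.b])
                gs.extend([dw, db])
            opt.step(params, gs)
            batch_losses.append(loss)

        p_val = net.predict(X_val)
        if classification:
            val_loss = weighted_bce(y_val, p_val, cw) + l1_term(net)
            val_auc = _safe_auc(y_val, p_val)
        else:
            val_loss = mse(y_val, p_val) + l1_term(net)
            val_auc = float("nan")
        if not np.isfinite(val_loss):
            raise TrainingDiverged(
                f"non-finite validation loss at epoch {epoch} "
                f"(optimizer={cfg.optimizer}, lr={cfg.learning_rate})"
            )
        rows.append({
            "epoch": epoch,
            "train_loss": float(np.mean(batch_losses)),
            "val_loss": val_loss,
            "val_auc": val_auc,
        })
        if stopper.update(epoch, val_loss):
            best_state = net.get_state()
        if stopper.stop:
            stopped_epoch = epoch
            break
    net.set_state(best_state)
    history = pd.DataFrame(rows)
    return TrainResult(net=net, history=history,
                       best_epoch=stopper.best_epoch, stopped_epoch=stopped_epoch)


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------

#: optimizer settings explored during model selection
GRID_OPTIMIZERS = (("adadelta", 1.0), ("adam", 0.01), ("adam", 0.001), ("adam", 0.0001))
#: de-duplicated L1 penalty grid
GRID_PENALTIES = (0.1, 0.001, 0.00001, 0.0)


def hyperparameter_grid(**overrides) -> list[TrainConfig]:
    """Cartesian product of optimizer settings and L1 penalties (16 configs)."""
    grid = []
    for opt, lr in GRID_OPTIMIZERS:
        for pen in GRID_PENALTIES:
            grid.append(TrainConfig(optimizer=opt, learning_rate=lr,
                                    l1_penalty=pen, **overrides))
    return grid


def select_best(configs: Sequence[TrainConfig], val_aucs: Sequence[float]) -> TrainConfig:
    """argmax validation AUC; exact ties break toward the lower L1 penalty."""
    if len(configs) != len(val_aucs) or not configs:
        raise ValueError("configs and val_aucs must be parallel and non-empty")
    order = sorted(range(len(configs)),
                   key=lambda i: (-val_aucs[i], configs[i].l1_penalty))
    return configs[order[0]]
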