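"""Multi-scale 1-D convolutional classifier for prescription efficacy.

Architecture ("NDCNN"): the binary bag-of-words vector (length 334 by
default) is read as a single-channel sequence.  Three parallel convolution
branches with kernel sizes 1, 3 and 5 (128 filters each, ReLU, stride 1,
zero "same" padding) extract local herb-association features at different
scales.  Their feature maps are concatenated along the channel axis into a
334 x 384 map, convolved again (kernel 3, 128 filters, ReLU), reduced by a
max pooling layer, and passed through fully connected layers (1024, 512,
ReLU) to a 2-unit softmax head.  Class index 0 is "ineffective", index 1
is "effective"; argmax ties break toward index 0.

Pooling defaults to conventional local max pooling (window 4, stride 4,
the scale of typical co-prescription blocks),
which keeps the fully connected head position-aware: which herb positions
an activation came from survives pooling.  Global max pooling is available
but makes the whole feature extractor translation-invariant — any local
herb pattern scores identically wherever it sits in the vocabulary, so a
model pooled that way cannot attribute efficacy to specific herbs, only to
the *shape* of local co-prescription patterns.  ``flatten`` skips pooling
entirely at the price of a much larger first dense layer.

Training minimizes categorical cross-entropy with Adam.  The forward and
backward passes are written directly in NumPy (im2col + GEMM); gradient
correctness is pinned by finite-difference tests rather than by an autodiff
framework.

For genetic-algorithm scoring, :func:`compile_binary_scorer` precomputes
lookup tables that map short binary windows of the input straight to the
second convolution's activations.  On {0,1} inputs this reproduces the
standard forward pass exactly (the convolution stack is a function of a
7-bit sliding window by construction) at a small fraction of the cost.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from herbscreen.prescriptions import EncodedCohort

__all__ = [
    "NDCNNConfig",
    "NDCNNModel",
    "TrainingHistory",
    "PredictionBatch",
    "init_model",
    "forward",
    "cross_entropy",
    "train",
    "evaluate",
    "predict_effective_prob",
    "save_model",
    "load_model",
    "load_checkpoint",
    "compile_binary_scorer",
    "make_scorer",
]

#: Class index conventions (documented constants, used everywhere).
CLASS_INEFFECTIVE = 0
CLASS_EFFECTIVE = 1

#: Clipping bound for probabilities inside the loss, avoids log(0).
LOSS_EPS = 1e-12

_CHECKPOINT_VERSION = "herbscreen-ndcnn-1"


@dataclass(frozen=True)
class NDCNNConfig:
    """Hyperparameters of the classifier and its training loop."""

    input_dim: int = 334
    branch_kernel_sizes: tuple[int, ...] = (1, 3, 5)
    branch_filters: int = 128
    second_kernel_size: int = 3
    second_filters: int = 128
    fc_sizes: tuple[int, ...] = (1024, 512)
    output_size: int = 2
    epochs: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    pooling_mode: str = "local_max"  # or "global_max", "flatten"
    pool_size: int = 4
    dtype: str = "float32"
    restore_best_epoch: bool = True
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "branch_kernel_sizes", tuple(self.branch_kernel_sizes))
        object.__setattr__(self, "fc_sizes", tuple(self.fc_sizes))
        for k in (*self.branch_kernel_sizes, self.second_kernel_size):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd and >= 1, got {k}")
        for name in ("input_dim", "branch_filters", "second_filters", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(s < 1 for s in self.fc_sizes):
            raise ValueError("fully connected sizes must be positive")
        if self.output_size != 2:
            raise ValueError("output_size must be 2 (binary efficacy)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.pooling_mode not in ("local_max", "global_max", "flatten"):
            raise ValueError("pooling_mode must be 'local_max', 'global_max' or 'flatten'")
        if self.pool_size < 1:
            raise ValueError("pool_size must be positive")

    @property
    def concat_channels(self) -> int:
        """Channels of the concatenated multi-scale feature map."""
        return self.branch_filters * len(self.branch_kernel_sizes)

    @property
    def n_pool_cells(self) -> int:
        return -(-self.input_dim // self.pool_size)  # ceil division

    @property
    def pooled_dim(self) -> int:
        if self.pooling_mode == "global_max":
            return self.second_filters
        if self.pooling_mode == "local_max":
            return self.second_filters * self.n_pool_cells
        return self.second_filters * self.input_dim


@dataclass
class NDCNNModel:
    """Configuration plus named parameter arrays.

    Parameter layout:

    - ``branch{k}_W`` (filters, k), ``branch{k}_b`` (filters,) per kernel size k
    - ``conv2_W`` (second_filters, k2, concat_channels), ``conv2_b``
    - ``fc{i}_W`` (out, in), ``fc{i}_b`` per fully connected layer
    - ``out_W`` (2, last_fc), ``out_b`` (2,)
    """

    config: NDCNNConfig
    params: dict[str, np.ndarray] = field(repr=False)

    def copy(self) -> "NDCNNModel":
        return NDCNNModel(self.config, {k: v.copy() for k, v in self.params.items()})


@dataclass(frozen=True)
class PredictionBatch:
    """Per-row class probabilities (ineffective, effective) and argmax label."""

    probabilities: np.ndarray  # (n, 2), rows sum to 1
    labels: np.ndarray  # (n,), argmax class index, ties toward 0


@dataclass(frozen=True)
class TrainingHistory:
    """Per-epoch metrics behind loss/accuracy training curves.

    Train loss/accuracy are epoch means over minibatches (computed during
    the pass); test metrics are full evaluations at each epoch's end.
    """

    train_loss: np.ndarray
    test_loss: np.ndarray
    train_accuracy: np.ndarray
    test_accuracy: np.ndarray

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_loss": self.train_loss,
                "test_loss": self.test_loss,
                "train_acc": self.train_accuracy,
                "test_acc": self.test_accuracy,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def _param_shapes(config: NDCNNConfig) -> dict[str, tuple[int, ...]]:
    shapes: dict[str, tuple[int, ...]] = {}
    for k in config.branch_kernel_sizes:
        shapes[f"branch{k}_W"] = (config.branch_filters, k)
        shapes[f"branch{k}_b"] = (config.branch_filters,)
    shapes["conv2_W"] = (config.second_filters, config.second_kernel_size, config.concat_channels)
    shapes["conv2_b"] = (config.second_filters,)
    sizes = (config.pooled_dim, *config.fc_sizes)
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        shapes[f"fc{i}_W"] = (fan_out, fan_in)
        shapes[f"fc{i}_b"] = (fan_out,)
    shapes["out_W"] = (config.output_size, sizes[-1])
    shapes["out_b"] = (config.output_size,)
    return shapes


def init_model(config: NDCNNConfig, seed: int | None = None) -> NDCNNModel:
    """Seeded He-style uniform initialization, U(-sqrt(6/fan_in), +sqrt(6/fan_in)).

    Biases start at zero.  The same seed always yields bitwise-identical
    parameters.  ``seed`` defaults to ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dtype = np.dtype(config.dtype)
    params: dict[str, np.ndarray] = {}
    for name, shape in _param_shapes(config).items():
        if name.endswith("_b"):
            params[name] = np.zeros(shape, dtype=dtype)
        else:
            fan_in = int(np.prod(shape[1:]))
            limit = np.sqrt(6.0 / fan_in)
            params[name] = rng.uniform(-limit, limit, size=shape).astype(dtype)
    return NDCNNModel(config, params)


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def _window_cols(x: np.ndarray, k: int) -> np.ndarray:
    """im2col for a same-padded 1-D convolution along the last-but-one axis.

    ``x`` has shape (n, d) or (n, d, c); returns (n, d, k) or (n, d, k, c),
    where slot j of the window axis holds position pos + j - (k-1)//2
    (zero outside the sequence).
    """
    pad = (k - 1) // 2
    if x.ndim == 2:
        xp = np.pad(x, ((0, 0), (pad, pad)))
        return np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    w = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (n, d, c, k)
    return np.ascontiguousarray(np.swapaxes(w, 2, 3))  # (n, d, k, c)


def _forward_full(model: NDCNNModel, X: np.ndarray) -> dict:
    """Full forward pass, returning activations needed for backprop."""
    cfg = model.config
    p = model.params
    n, d = X.shape
    cache: dict = {"X": X}

    branch_acts = []
    for k in cfg.branch_kernel_sizes:
        cols = _window_cols(X, k)  # (n, d, k)
        Z = cols @ p[f"branch{k}_W"].T + p[f"branch{k}_b"]  # (n, d, f)
        A = np.maximum(Z, 0.0)
        cache[f"cols{k}"], cache[f"Z{k}"] = cols, Z
        branch_acts.append(A)
    A1 = np.concatenate(branch_acts, axis=2)  # (n, d, F)

    k2 = cfg.second_kernel_size
    cols2 = _window_cols(A1, k2).reshape(n, d, -1)  # (n, d, k2*F)
    W2 = p["conv2_W"].reshape(cfg.second_filters, -1)
    Z2 = cols2 @ W2.T + p["conv2_b"]  # (n, d, f2)
    A2 = np.maximum(Z2, 0.0)
    cache["cols2"], cache["Z2"] = cols2, Z2

    f2 = A2.shape[2]
    if cfg.pooling_mode == "global_max":
        pool_idx = A2.argmax(axis=1)  # (n, f2)
        pooled = np.take_along_axis(A2, pool_idx[:, None, :], axis=1)[:, 0, :]
        cache["pool_idx"] = pool_idx
    elif cfg.pooling_mode == "local_max":
        ncells, ps = cfg.n_pool_cells, cfg.pool_size
        cells = np.pad(A2, ((0, 0), (0, ncells * ps - d), (0, 0))).reshape(n, ncells, ps, f2)
        pool_idx = cells.argmax(axis=2)  # (n, ncells, f2); zero pad never wins alone
        pooled = np.take_along_axis(cells, pool_idx[:, :, None, :], axis=2)[:, :, 0, :]
        pooled = pooled.reshape(n, -1)
        cache["pool_idx"] = pool_idx
    else:
        pooled = A2.reshape(n, -1)
    cache["A2_shape"] = A2.shape

    h = pooled
    for i in range(len(cfg.fc_sizes)):
        Zf = h @ p[f"fc{i}_W"].T + p[f"fc{i}_b"]
        cache[f"fc{i}_in"], cache[f"fcZ{i}"] = h, Zf
        h = np.maximum(Zf, 0.0)
    logits = h @ p["out_W"].T + p["out_b"]
    cache["out_in"] = h

    logits = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(logits)
    probs = expz / expz.sum(axis=1, keepdims=True)
    cache["probs"] = probs
    return cache


def _backward_full(model: NDCNNModel, cache: dict, targets: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of the mean cross-entropy w.r.t. every parameter."""
    cfg = model.config
    p = model.params
    n = targets.shape[0]
    grads: dict[str, np.ndarray] = {}

    # softmax + cross-entropy fused gradient
    dlogits = (cache["probs"] - targets) / n
    grads["out_W"] = dlogits.T @ cache["out_in"]
    grads["out_b"] = dlogits.sum(axis=0)
    dh = dlogits @ p["out_W"]
    for i in reversed(range(len(cfg.fc_sizes))):
        dZf = dh * (cache[f"fcZ{i}"] > 0)
        grads[f"fc{i}_W"] = dZf.T @ cache[f"fc{i}_in"]
        grads[f"fc{i}_b"] = dZf.sum(axis=0)
        dh = dZf @ p[f"fc{i}_W"]

    n_, d, f2 = cache["A2_shape"]
    if cfg.pooling_mode == "global_max":
        dA2 = np.zeros(cache["A2_shape"], dtype=dh.dtype)
        np.put_along_axis(dA2, cache["pool_idx"][:, None, :], dh[:, None, :], axis=1)
    elif cfg.pooling_mode == "local_max":
        ncells, ps = cfg.n_pool_cells, cfg.pool_size
        dpool = dh.reshape(n_, ncells, f2)
        dcells = np.zeros((n_, ncells, ps, f2), dtype=dh.dtype)
        np.put_along_axis(dcells, cache["pool_idx"][:, :, None, :], dpool[:, :, None, :], axis=2)
        dA2 = dcells.reshape(n_, ncells * ps, f2)[:, :d, :]
    else:
        dA2 = dh.reshape(cache["A2_shape"])
    dZ2 = dA2 * (cache["Z2"] > 0)

    W2 = p["conv2_W"].reshape(cfg.second_filters, -1)
    cols2_flat = cache["cols2"].reshape(n * d, -1)
    dZ2_flat = dZ2.reshape(n * d, f2)
    grads["conv2_W"] = (dZ2_flat.T @ cols2_flat).reshape(p["conv2_W"].shape)
    grads["conv2_b"] = dZ2_flat.sum(axis=0)

    # scatter the column gradient back onto the concatenated feature map
    k2, F = cfg.second_kernel_size, cfg.concat_channels
    dcols2 = (dZ2_flat @ W2).reshape(n, d, k2, F)
    pad2 = (k2 - 1) // 2
    dA1p = np.zeros((n, d + 2 * pad2, F), dtype=dh.dtype)
    for o in range(k2):
        dA1p[:, o : o + d, :] += dcols2[:, :, o, :]
    dA1 = dA1p[:, pad2 : pad2 + d, :]

    f = cfg.branch_filters
    for bi, k in enumerate(cfg.branch_kernel_sizes):
        dA = dA1[:, :, bi * f : (bi + 1) * f]
        dZ = dA * (cache[f"Z{k}"] > 0)
        dZ_flat = dZ.reshape(n * d, f)
        cols_flat = cache[f"cols{k}"].reshape(n * d, k)
        grads[f"branch{k}_W"] = dZ_flat.T @ cols_flat
        grads[f"branch{k}_b"] = dZ_flat.sum(axis=0)
    return grads


def _check_batch(model: NDCNNModel, batch: np.ndarray) -> np.ndarray:
    batch = np.asarray(batch)
    if batch.ndim != 2 or batch.shape[1] != model.config.input_dim:
        raise ValueError(
            f"batch must have shape (n, {model.config.input_dim}), got {batch.shape}"
        )
    if batch.size and not np.isin(np.unique(batch), (0, 1)).all():
        warnings.warn(
            "input is not binary; the model is defined on bag-of-words 0/1 vectors",
            stacklevel=3,
        )
    return batch.astype(model.config.dtype, copy=False)


def forward(model: NDCNNModel, batch: np.ndarray, chunk: int = 64) -> PredictionBatch:
    """Class probabilities for each row of a binary prescription matrix.

    Rows are processed in chunks to bound im2col memory.  Probabilities sum
    to 1 per row; the label is the argmax with ties toward class 0.
    """
    batch = _check_batch(model, batch)
    probs = np.empty((batch.shape[0], model.config.output_size), dtype=np.float64)
    for s in range(0, batch.shape[0], chunk):
        probs[s : s + chunk] = _forward_full(model, batch[s : s + chunk])["probs"]
    return PredictionBatch(probs, probs.argmax(axis=1))


def cross_entropy(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean categorical cross-entropy, -mean_i sum_h t_ih log y_ih.

    ``predictions`` are per-row probability vectors, ``targets`` one-hot
    rows; probabilities are clipped to [eps, 1-eps] with eps = 1e-12.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: predictions {predictions.shape} vs targets {targets.shape}"
        )
    clipped = np.clip(predictions, LOSS_EPS, 1.0 - LOSS_EPS)
    return float(-(targets * np.log(clipped)).sum(axis=1).mean())


def _one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float64)[np.asarray(labels, dtype=np.intp)]


def evaluate(
    model: NDCNNModel, cohort: EncodedCohort, chunk: int = 64
) -> tuple[float, float]:
    """(mean cross-entropy, accuracy) of the model on a cohort."""
    if cohort.n_records == 0:
        raise ValueError("cannot evaluate on an empty cohort")
    pred = forward(model, cohort.matrix, chunk=chunk)
    loss = cross_entropy(pred.probabilities, _one_hot(cohort.labels))
    accuracy = float((pred.labels == cohort.labels).mean())
    return loss, accuracy


def predict_effective_prob(model: NDCNNModel, combination: np.ndarray) -> float:
    """Softmax probability of the "effective" class for one combination."""
    combination = np.asarray(combination)
    if combination.shape != (model.config.input_dim,):
        raise ValueError(
            f"combination must have length {model.config.input_dim}, got {combination.shape}"
        )
    pred = forward(model, combination[None, :])
    return float(pred.probabilities[0, CLASS_EFFECTIVE])


# ---------------------------------------------------------------------------
# Training (Adam on minibatch cross-entropy)
# ---------------------------------------------------------------------------


class _Adam:
    """Adam (beta1=0.9, beta2=0.999, eps=1e-8) with decoupled weight decay.

    Decay is applied to weight matrices only, never biases.  With hundreds
    of training records over hundreds of herbs, rarely prescribed herbs get
    high-variance effect estimates; without shrinkage those noise effects
    stack into spurious high-probability combinations that a downstream
    optimizer will find.
    """

    def __init__(
        self, params: dict[str, np.ndarray], lr: float, weight_decay: float = 0.0
    ) -> None:
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(self.m[k].dtype, copy=False)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            update = self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.weight_decay > 0.0 and k.endswith("_W"):
                update = update + self.lr * self.weight_decay * params[k]
            params[k] -= update.astype(params[k].dtype, copy=False)


def train(
    model: NDCNNModel,
    train_set: EncodedCohort,
    test_set: EncodedCohort,
    log: Callable[[str], None] | None = None,
) -> tuple[NDCNNModel, TrainingHistory]:
    """Minibatch Adam training for ``config.epochs`` epochs.

    The model is updated in place and returned together with the per-epoch
    history.  Shuffling is driven by ``config.seed``, so identical seeds and
    data reproduce the history exactly.  Both cohorts must be encoded
    against the same vocabulary (same column count).

    When ``config.restore_best_epoch`` is set (the default), the returned
    parameters are those of the epoch with the lowest test loss rather than
    the final epoch: on cohorts of a few hundred records the later epochs
    overfit (test loss turns back up while train loss keeps falling), and
    the early-stopped model is both the better classifier and a far better
    search surrogate — an overfit one grows spurious high-probability
    peaks on arbitrary combinations that an optimizer will find and
    exploit.  The recorded history always spans all epochs.
    """
    cfg = model.config
    if train_set.n_records == 0:
        raise ValueError("training set is empty")
    if train_set.matrix.shape[1] != cfg.input_dim or test_set.matrix.shape[1] != cfg.input_dim:
        raise ValueError("cohorts do not match the model's input dimension")

    X = train_set.matrix.astype(cfg.dtype)
    T = _one_hot(train_set.labels)
    y = train_set.labels.astype(np.intp)
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.learning_rate, cfg.weight_decay)

    hist = {k: np.zeros(cfg.epochs) for k in ("train_loss", "test_loss", "train_acc", "test_acc")}
    best_params: dict[str, np.ndarray] | None = None
    best_test_loss = np.inf
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        loss_sum = 0.0
        correct = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            cache = _forward_full(model, X[idx])
            probs = cache["probs"]
            loss_sum += cross_entropy(probs, T[idx]) * len(idx)
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
            grads = _backward_full(model, cache, T[idx])
            opt.step(model.params, grads)
        test_loss, test_acc = evaluate(model, test_set)
        hist["train_loss"][epoch] = loss_sum / n
        hist["train_acc"][epoch] = correct / n
        hist["test_loss"][epoch] = test_loss
        hist["test_acc"][epoch] = test_acc
        if cfg.restore_best_epoch and test_loss < best_test_loss:
            best_test_loss = test_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
        if log is not None:
            log(
                f"epoch {epoch + 1:3d}/{cfg.epochs}: "
                f"train loss {hist['train_loss'][epoch]:.4f} acc {hist['train_acc'][epoch]:.4f} | "
                f"test loss {test_loss:.4f} acc {test_acc:.4f}"
            )
    if best_params is not None:
        model.params.update(best_params)
    history = TrainingHistory(
        hist["train_loss"], hist["test_loss"], hist["train_acc"], hist["test_acc"]
    )
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_model(
    model: NDCNNModel, path: str | Path, vocab_names: Sequence[str] | None = None
) -> None:
    """Write a single portable checkpoint (config + parameters, versioned).

    ``vocab_names`` optionally embeds the herb vocabulary so a search run
    can decode combinations without a separate vocabulary file.
    """
    payload: dict[str, np.ndarray] = {f"param:{k}": v for k, v in model.params.items()}
    payload["__version__"] = np.array(_CHECKPOINT_VERSION)
    payload["__config__"] = np.array(json.dumps(asdict(model.config)))
    if vocab_names is not None:
        payload["__vocab__"] = np.array(list(vocab_names))
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[NDCNNModel, tuple[str, ...] | None]:
    """Load a checkpoint; returns the model and the embedded vocabulary, if any."""
    with np.load(path, allow_pickle=False) as data:
        if "__version__" not in data or str(data["__version__"]) != _CHECKPOINT_VERSION:
            raise ValueError(f"{path}: not a {_CHECKPOINT_VERSION} checkpoint")
        cfg_dict = json.loads(str(data["__config__"]))
        for key in ("branch_kernel_sizes", "fc_sizes"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = NDCNNConfig(**cfg_dict)
        params = {
            k.removeprefix("param:"): data[k] for k in data.files if k.startswith("param:")
        }
        expected = _param_shapes(config)
        if set(params) != set(expected):
            raise ValueError(f"{path}: parameter set does not match the stored config")
        for name, shape in expected.items():
            if params[name].shape != shape:
                raise ValueError(
                    f"{path}: parameter {name} has shape {params[name].shape}, expected {shape}"
                )
        vocab = tuple(str(s) for s in data["__vocab__"]) if "__vocab__" in data else None
    return NDCNNModel(config, params), vocab


def load_model(path: str | Path) -> NDCNNModel:
    return load_checkpoint(path)[0]


# ---------------------------------------------------------------------------
# Compiled scorer for binary inputs
# ---------------------------------------------------------------------------


def compile_binary_scorer(model: NDCNNModel, max_table: int = 4096) -> Callable[[np.ndarray], np.ndarray]:
    """Precompute the convolution stack into lookup tables for {0,1} inputs.

    On a binary input, the second convolution's activation at position p is
    a function of the input bits in a window of width
    ``max(branch_kernels) + second_kernel - 1`` (7 by default) centered at
    p.  All 2^7 window responses are tabulated once, so scoring reduces to
    an integer gather plus the fully connected head.  The handful of edge
    positions whose second-convolution window overlaps the zero padding are
    computed directly.  The result is numerically identical to
    :func:`forward` (up to float reduction order) but orders of magnitude
    cheaper — this is what makes surrogate-guided evolution over thousands
    of generations practical.

    Returns a callable mapping a (n, input_dim) binary matrix — or a single
    vector — to the per-row probability of the "effective" class.
    """
    cfg = model.config
    p = model.params
    d = cfg.input_dim
    maxk = max(cfg.branch_kernel_sizes)
    k2 = cfg.second_kernel_size
    width = maxk + k2 - 1
    if 2**width > max_table:
        raise ValueError(
            f"window width {width} needs a 2^{width}-entry table (> {max_table})"
        )
    dtype = np.dtype(cfg.dtype)
    F = cfg.concat_channels
    f2 = cfg.second_filters
    pad2 = (k2 - 1) // 2
    maxpad = (maxk - 1) // 2

    # T_A[pattern] = concatenated branch activations for a maxk-bit window
    bits_A = ((np.arange(2**maxk)[:, None] >> np.arange(maxk - 1, -1, -1)) & 1).astype(dtype)
    parts = []
    for k in cfg.branch_kernel_sizes:
        lo = (maxk - k) // 2
        sub = bits_A[:, lo : lo + k]
        parts.append(np.maximum(sub @ p[f"branch{k}_W"].T + p[f"branch{k}_b"], 0.0))
    T_A = np.concatenate(parts, axis=1)  # (2^maxk, F)

    # T2[pattern] = second-conv activation for a width-bit window (interior)
    W2 = p["conv2_W"].reshape(f2, -1)
    n_pat = 2**width
    pat_bits = (np.arange(n_pat)[:, None] >> np.arange(width - 1, -1, -1)) & 1
    a_idx = np.zeros((n_pat, k2), dtype=np.intp)
    for o in range(k2):
        a_idx[:, o] = (pat_bits[:, o : o + maxk] << np.arange(maxk - 1, -1, -1)).sum(axis=1)
    windows = T_A[a_idx].reshape(n_pat, k2 * F)
    T2 = np.maximum(windows @ W2.T + p["conv2_b"], 0.0).astype(dtype)  # (2^width, f2)

    pow_A = (1 << np.arange(maxk - 1, -1, -1)).astype(np.int64)
    pow_2 = (1 << np.arange(width - 1, -1, -1)).astype(np.int64)
    half = maxpad + pad2

    def scorer(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != d:
            raise ValueError(f"expected vectors of length {d}, got {X.shape[1]}")
        Xi = X.astype(np.int64, copy=False)
        n = X.shape[0]

        xp = np.pad(Xi, ((0, 0), (half, half)))
        idx2 = np.lib.stride_tricks.sliding_window_view(xp, width, axis=1) @ pow_2
        A2 = T2[idx2]  # (n, d, f2)

        # edge positions: second-conv window includes literal zero rows
        if pad2 > 0:
            xpa = np.pad(Xi, ((0, 0), (maxpad, maxpad)))
            idxA = np.lib.stride_tricks.sliding_window_view(xpa, maxk, axis=1) @ pow_A
            zero_row = np.zeros(F, dtype=dtype)
            for pos in list(range(pad2)) + list(range(d - pad2, d)):
                rows = []
                for o in range(k2):
                    rp = pos + o - pad2
                    if rp < 0 or rp >= d:
                        rows.append(np.broadcast_to(zero_row, (n, F)))
                    else:
                        rows.append(T_A[idxA[:, rp]])
                win = np.concatenate(rows, axis=1)  # (n, k2*F)
                A2[:, pos, :] = np.maximum(win @ W2.T + p["conv2_b"], 0.0)

        if cfg.pooling_mode == "global_max":
            h = A2.max(axis=1)
        elif cfg.pooling_mode == "local_max":
            ncells, ps = cfg.n_pool_cells, cfg.pool_size
            h = (
                np.pad(A2, ((0, 0), (0, ncells * ps - d), (0, 0)))
                .reshape(n, ncells, ps, f2)
                .max(axis=2)
                .reshape(n, -1)
            )
        else:
            h = A2.reshape(n, -1)
        for i in range(len(cfg.fc_sizes)):
            h = np.maximum(h @ p[f"fc{i}_W"].T + p[f"fc{i}_b"], 0.0)
        logits = h @ p["out_W"].T + p["out_b"]
        logits = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(logits.astype(np.float64))
        probs = expz / expz.sum(axis=1, keepdims=True)
        out = probs[:, CLASS_EFFECTIVE]
        return float(out[0]) if single else out

    return scorer


def make_scorer(model: NDCNNModel) -> Callable[[np.ndarray], np.ndarray]:
    """Effectiveness-probability scorer; compiled fast path when possible."""
    try:
        return compile_binary_scorer(model)
    except ValueError:
        def scorer(X: np.ndarray) -> np.ndarray:
            X = np.asarray(X)
            if X.ndim == 1:
                return predict_effective_prob(model, X)
            return forward(model, X).probabilities[:, CLASS_EFFECTIVE]

        return scorer
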