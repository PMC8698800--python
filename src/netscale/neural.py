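"""Data splitting and the MLP regressor mapping contact vectors to distances.

The regressor is a fully-connected network (ReLU hidden layers, linear
output, inverted dropout after every hidden layer) trained with minibatch
AMSGrad on a mean-squared-error loss.  Forward and backward passes are
plain numpy; at the problem sizes this package targets a CPU run takes
minutes.  Training is exactly reproducible for a fixed (data, config,
seed) triple on one device.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Default lower bound (Angstrom) applied to predicted distances before
#: reconstruction; the MDS embedding requires positive dissimilarities.
DISTANCE_FLOOR = 0.5


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test frame-id sets covering all frames."""

    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    seed: int

    def __post_init__(self):
        all_ids = np.concatenate([self.train_ids, self.val_ids, self.test_ids])
        if len(np.unique(all_ids)) != len(all_ids):
            raise ValueError("split sets are not pairwise disjoint")
        if not np.array_equal(np.sort(all_ids), np.arange(len(all_ids))):
            raise ValueError("split sets do not cover frames 0..n-1 exactly")

    @property
    def n_frames(self) -> int:
        return len(self.train_ids) + len(self.val_ids) + len(self.test_ids)


def split_frames(n_frames: int, fractions=(0.72, 0.08, 0.20),
                 seed: int = 0) -> SplitSpec:
    """Random train/validation/test split with sizes rounded to frames.

    ``fractions`` is (train, validation, test) and must sum to 1.  The
    default allocates 72% for training, 8% for validation and 20% for
    testing.  Reproducible for a fixed seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError("fractions must sum to 1")
    if n_frames < 3:
        raise ValueError("need at least 3 frames to split")
    n_train = int(round(fractions[0] * n_frames))
    n_val = int(round(fractions[1] * n_frames))
    n_train = min(n_train, n_frames)
    n_val = min(n_val, n_frames - n_train)
    perm = np.random.default_rng(seed).permutation(n_frames)
    return SplitSpec(
        train_ids=np.sort(perm[:n_train]),
        val_ids=np.sort(perm[n_train:n_train + n_val]),
        test_ids=np.sort(perm[n_train + n_val:]),
        seed=seed,
    )


def kfold_splits(n_frames: int, k: int = 5, seed: int = 0,
                 val_fraction: float = 0.1) -> list[SplitSpec]:
    """k-fold cross-validation splits: each frame tests in exactly one fold.

    Within each fold the non-test frames are subdivided into train and
    validation sets (``val_fraction`` of the non-test frames), mirroring
    the single-split train:validation ratio.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_frames:
        raise ValueError(f"k={k} exceeds n_frames={n_frames}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_frames)
    folds = np.array_split(perm, k)
    splits = []
    for f in range(k):
        test_ids = folds[f]
        rest = np.concatenate([folds[g] for g in range(k) if g != f])
        rest = rng.permutation(rest)
        n_val = int(round(val_fraction * len(rest)))
        splits.append(SplitSpec(
            train_ids=np.sort(rest[n_val:]),
            val_ids=np.sort(rest[:n_val]),
            test_ids=np.sort(test_ids),
            seed=seed,
        ))
    return splits


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and optimisation hyperparameters of the upscaler."""

    hidden_sizes: list = field(default_factory=lambda: [2000, 2000, 2000, 8000])
    activation: str = "relu"
    dropout: float = 0.2
    optimizer: str = "amsgrad"
    loss: str = "mse"
    batch_size: int = 50
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be nonempty and positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only relu hidden activation is supported")
        if self.optimizer != "amsgrad":
            raise ValueError("only the AMSGrad optimizer is supported")
        if self.loss != "mse":
            raise ValueError("only mean squared error loss is supported")

    def to_dict(self) -> dict:
        return {
            "hidden_sizes": list(self.hidden_sizes),
            "activation": self.activation,
            "dropout": self.dropout,
            "optimizer": self.optimizer,
            "loss": self.loss,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class Upscaler:
    """MLP regressor from PSN adjacency vectors to PID vectors."""

    def __init__(self, config: ModelConfig, input_dim: int, output_dim: int,
                 atom_fingerprint: str | None = None):
        if input_dim <= 0 or output_dim <= 0:
            raise ValueError("dimensions must be positive")
        self.config = config
        self.input_dim = input_dim
        self.output_dim = output_dim
        self.atom_fingerprint = atom_fingerprint
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        rng = np.random.default_rng(config.seed)
        sizes = [input_dim] + list(config.hidden_sizes) + [output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialisation for relu
            self.weights.append(rng.normal(0.0, scale, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    # -- forward/backward ---------------------------------------------------

    def _forward(self, X, rng=None):
        """Forward pass; with *rng* dropout is active (training mode)."""
        p = self.config.dropout
        activations = [np.asarray(X, dtype=np.float64)]
        masks = []
        h = activations[0]
        n_hidden = len(self.weights) - 1
        for layer in range(n_hidden):
            z = h @ self.weights[layer] + self.biases[layer]
            h = np.maximum(z, 0.0)
            if rng is not None and p > 0:
                mask = (rng.random(h.shape) >= p) / (1.0 - p)
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            activations.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        activations.append(out)
        return activations, masks

    def _backward(self, activations, masks, Y):
        batch = activations[0].shape[0]
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        # MSE averaged over batch and output dimensions
        delta = 2.0 * (activations[-1] - Y) / (batch * self.output_dim)
        grads_w[-1] = activations[-2].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        for layer in range(len(self.weights) - 2, -1, -1):
            delta = delta @ self.weights[layer + 1].T
            if masks[layer] is not None:
                delta = delta * masks[layer]
            delta = delta * (activations[layer + 1] > 0)
            grads_w[layer] = activations[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
        return grads_w, grads_b

    def evaluate_loss(self, X, Y) -> float:
        """Mean squared error at inference (dropout disabled)."""
        activations, _ = self._forward(X)
        return float(np.mean((activations[-1] - Y) ** 2))


def build_model(config: ModelConfig, input_dim: int, output_dim: int,
                atom_fingerprint: str | None = None) -> Upscaler:
    """Construct an untrained upscaler with seeded initial weights."""
    return Upscaler(config, input_dim, output_dim, atom_fingerprint)


class _AMSGrad:
    """AMSGrad variant of adaptive moment estimation."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.vhat = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2 ** self.t) / (1 - self.beta1 ** self.t)
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
            p -= lr_t * self.m[i] / (np.sqrt(self.vhat[i]) + self.eps)


def train(model: Upscaler, X_train, Y_train, X_val=None, Y_val=None) -> Upscaler:
    """Train in place with minibatch AMSGrad on the MSE loss.

    Records per-epoch train loss (mean over minibatch losses) and, if a
    validation set is given, the full-batch validation loss.  Aborts with
    a diagnostic if the loss turns non-finite.
    """
    cfg = model.config
    X_train = np.asarray(X_train, dtype=np.float64)
    Y_train = np.asarray(Y_train, dtype=np.float64)
    if X_train.shape[1] != model.input_dim:
        raise ValueError("X_train width does not match model input_dim")
    if Y_train.shape[1] != model.output_dim:
        raise ValueError("Y_train width does not match model output_dim")
    params = model.weights + model.biases
    opt = _AMSGrad(params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = X_train.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X_train[idx], Y_train[idx]
            activations, masks = model._forward(xb, rng=rng)
            loss = float(np.mean((activations[-1] - yb) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch + 1}")
            batch_losses.append(loss)
            grads_w, grads_b = model._backward(activations, masks, yb)
            opt.step(params, grads_w + grads_b)
        model.history["train_loss"].append(float(np.mean(batch_losses)))
        if X_val is not None and len(X_val):
            model.history["val_loss"].append(model.evaluate_loss(X_val, Y_val))
    return model


def predict(model: Upscaler, adjacency_batch, floor: float = DISTANCE_FLOOR) -> np.ndarray:
    """Predict PID vectors for a batch of adjacency vectors.

    Inference is deterministic (dropout disabled).  Predicted distances
    below *floor* (Angstrom) are clamped up to it — the distance-geometry
    embedding downstream needs positive dissimilarities — and the number
    of clamped entries is logged.
    """
    X = np.atleast_2d(np.asarray(adjacency_batch, dtype=np.float64))
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"input width {X.shape[1]} does not match model input_dim "
            f"{model.input_dim}"
        )
    activations, _ = model._forward(X)
    out = activations[-1]
    n_clamped = int(np.sum(out < floor))
    if n_clamped:
        logger.info("clamped %d predicted distances to the %.2f A floor",
                    n_clamped, floor)
    return np.maximum(out, floor)


def baseline_mean_predictor(Y_train) -> np.ndarray:
    """Constant predictor: the elementwise mean of the training targets."""
    Y_train = np.asarray(Y_train, dtype=np.float64)
    if Y_train.size == 0:
        raise ValueError("empty training targets")
    return Y_train.mean(axis=0)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: Upscaler, path: str | Path) -> None:
    """Persist config, weights, history and atom-table fingerprint."""
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    meta = {
        "config": model.config.to_dict(),
        "input_dim": model.input_dim,
        "output_dim": model.output_dim,
        "atom_fingerprint": model.atom_fingerprint,
        "history": model.history,
        "n_layers": len(model.weights),
    }
    np.savez(str(path), meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path, expect_fingerprint: str | None = None) -> Upscaler:
    """Load a checkpoint; refuses to run against a mismatched protein."""
    with np.load(str(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = Upscaler(
            ModelConfig.from_dict(meta["config"]),
            meta["input_dim"], meta["output_dim"],
            meta["atom_fingerprint"],
        )
        model.history = meta["history"]
        model.weights = [data[f"W{i}"] for i in range(meta["n_layers"])]
        model.biases = [data[f"b{i}"] for i in range(meta["n_layers"])]
    if (expect_fingerprint is not None
            and model.atom_fingerprint is not None
            and expect_fingerprint != model.atom_fingerprint):
        raise ValueError(
            "checkpoint was trained for a different atom table "
            f"(fingerprint {model.atom_fingerprint}, expected {expect_fingerprint})"
        )
    return model
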