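"""Per-block autoencoders: architecture rule, training recipe and metrics.

An autoencoder is fully determined by (shape, hl, bn, input_dim).  Layer
widths taper from the input to the bottleneck following

    n(l) = bn + (input_dim - bn) * (|l| / (hl + 1))**p,   p in {0, 0.5},

rounded to the nearest integer (half away from zero); p = 0 gives the
rectangular geometry, p = 0.5 the elliptic one.  Hidden layers use leaky
ReLU; the output layer uses r(x) = tanh(x) + 1 so reconstructions live in
(0, 2), matching the dosage scale.  Training is plain Adam on MSE for a
fixed number of epochs.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

SHAPE_P = {"rectangular": 0.0, "elliptic": 0.5}


@dataclass(frozen=True)
class ArchitectureSpec:
    """The (shape, hl, bn, input_dim) tuple that fixes an autoencoder."""

    input_dim: int
    hl: int
    bn: int
    shape: str = "elliptic"

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_P:
            raise ValueError(f"shape must be one of {sorted(SHAPE_P)}, got {self.shape!r}")
        if self.input_dim < 1 or self.hl < 1 or self.bn < 1:
            raise ValueError("input_dim, hl and bn must all be >= 1")
        if self.bn > self.input_dim:
            raise ValueError(f"bn={self.bn} exceeds input_dim={self.input_dim}")

    @property
    def n_layers(self) -> int:
        return 2 * self.hl + 3


@dataclass(frozen=True)
class TrainRecipe:
    """Fixed training recipe: 50 epochs, batch 32, Adam at 1e-4, MSE loss."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-4
    leaky_slope: float = 0.3
    seed: int = 0


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def layer_widths(spec: ArchitectureSpec) -> list[int]:
    """Widths of all 2*hl + 3 layers, input through bottleneck to output."""
    p = SHAPE_P[spec.shape]
    widths = []
    for l in range(-(spec.hl + 1), spec.hl + 2):
        if l == 0:
            widths.append(spec.bn)
        elif abs(l) == spec.hl + 1:
            widths.append(spec.input_dim)
        else:
            frac = abs(l) / (spec.hl + 1)
            widths.append(_round_half_away(spec.bn + (spec.input_dim - spec.bn) * frac ** p))
    return widths


def output_activation(x: np.ndarray) -> np.ndarray:
    """r(x) = tanh(x) + 1, mapping the reals onto the open interval (0, 2)."""
    return np.tanh(x) + 1.0


class DenseAutoencoder:
    """Sequential fully connected autoencoder on float64 numpy arrays.

    He-uniform weight init from a seeded generator; leaky ReLU everywhere
    except the output layer, which applies :func:`output_activation`.
    Deterministic for a fixed (seed, data, ordering).
    """

    def __init__(self, widths: Sequence[int], seed: int, leaky_slope: float = 0.3):
        self.widths = list(widths)
        self.leaky_slope = float(leaky_slope)
        self.bottleneck_layer = (len(self.widths) - 1) // 2  # index into post-layer activations
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.widths[:-1], self.widths[1:]):
            limit = math.sqrt(6.0 / fan_in)
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def n_weight_layers(self) -> int:
        return len(self.W)

    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.W, self.b))

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Post-activation values per layer; acts[0] is the input."""
        acts = [X]
        a = X
        last = self.n_weight_layers - 1
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if k == last:
                a = output_activation(z)
            else:
                a = np.where(z > 0, z, self.leaky_slope * z)
            acts.append(a)
        return acts

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[-1]

    def encode(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for k in range(self.bottleneck_layer):
            z = a @ self.W[k] + self.b[k]
            a = np.where(z > 0, z, self.leaky_slope * z)
        return a

    def _step(self, X: np.ndarray, lr: float, adam_state: dict) -> float:
        """One Adam step on the MSE of a minibatch; returns the batch loss."""
        acts = self._forward(X)
        yhat = acts[-1]
        n_el = yhat.size
        loss = float(np.mean((yhat - X) ** 2))
        delta = 2.0 * (yhat - X) / n_el          # dL/dyhat
        delta = delta * (1.0 - (yhat - 1.0) ** 2)  # through tanh+1: 1 - tanh^2
        gW = [np.empty(0)] * self.n_weight_layers
        gb = [np.empty(0)] * self.n_weight_layers
        for k in range(self.n_weight_layers - 1, -1, -1):
            gW[k] = acts[k].T @ delta
            gb[k] = delta.sum(axis=0)
            if k > 0:
                delta = delta @ self.W[k].T
                a_prev = acts[k]
                delta = delta * np.where(a_prev > 0, 1.0, self.leaky_slope)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        adam_state["t"] += 1
        t = adam_state["t"]
        for k in range(self.n_weight_layers):
            for name, param, grad in (("W", self.W[k], gW[k]), ("b", self.b[k], gb[k])):
                key = (name, k)
                m = adam_state["m"].setdefault(key, np.zeros_like(param))
                v = adam_state["v"].setdefault(key, np.zeros_like(param))
                m += (1 - beta1) * (grad - m)
                v += (1 - beta2) * (grad * grad - v)
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def fit(self, X: np.ndarray, recipe: TrainRecipe, shuffle_seed: int) -> list[float]:
        """Exactly ``recipe.epochs`` passes over ``X``; per-epoch mean losses."""
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(shuffle_seed)
        state = {"t": 0, "m": {}, "v": {}}
        n = X.shape[0]
        losses = []
        for _ in range(recipe.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, recipe.batch_size):
                batch = X[order[start:start + recipe.batch_size]]
                epoch_loss += self._step(batch, recipe.learning_rate, state) * batch.shape[0]
            losses.append(epoch_loss / n)
        return losses


@dataclass
class AccuracyBreakdown:
    """Overall SNP accuracy with its per-dosage decomposition."""

    overall: float
    by_dosage: dict[int, float]
    counts: dict[int, int]

    def __float__(self) -> float:
        return self.overall


@dataclass
class TrainedBlockModel:
    """A fitted per-block autoencoder plus its training/validation metrics."""

    spec: ArchitectureSpec
    model: DenseAutoencoder
    block_id: str
    train_mse: float
    val_mse: float
    train_acc: float
    val_acc: float
    loss_history: list[float] = field(default_factory=list)


def build_model(spec: ArchitectureSpec, recipe: TrainRecipe) -> DenseAutoencoder:
    """Untrained autoencoder with He-uniform weights seeded from the recipe."""
    return DenseAutoencoder(layer_widths(spec), seed=recipe.seed,
                            leaky_slope=recipe.leaky_slope)


def block_seed(global_seed: int, block_id: str) -> int:
    """Stable per-block seed below 2**31, derived from (seed, block id)."""
    return zlib.adler32(f"{global_seed}:{block_id}".encode()) % (2**31 - 1)


def round_dosage(pred: np.ndarray) -> np.ndarray:
    """Round predictions half-up to the nearest dosage in {0, 1, 2}."""
    return np.clip(np.floor(np.asarray(pred, dtype=float) + 0.5), 0, 2).astype(np.int16)


def snp_accuracy(predicted: np.ndarray, truth: np.ndarray) -> AccuracyBreakdown:
    """Fraction of entries whose rounded prediction equals the true dosage.

    Also reports accuracy restricted to each true dosage value (0/1/2).
    """
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    correct = round_dosage(predicted) == truth
    by_dosage, counts = {}, {}
    for d in (0, 1, 2):
        mask = truth == d
        counts[d] = int(mask.sum())
        by_dosage[d] = float(correct[mask].mean()) if counts[d] else float("nan")
    return AccuracyBreakdown(float(correct.mean()), by_dosage, counts)


def compression_ratio(bn: int, input_dim: int) -> float:
    """Compressed over original dimension: bn / input_dim."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    if not (1 <= bn <= input_dim):
        raise ValueError(f"need 1 <= bn <= input_dim, got bn={bn}, input_dim={input_dim}")
    return bn / input_dim


def train_block(
    spec: ArchitectureSpec,
    dosages: np.ndarray,
    recipe: TrainRecipe,
    val_index: Optional[np.ndarray] = None,
    val_frac: float = 0.2,
    block_id: str = "block",
) -> TrainedBlockModel:
    """Fit one autoencoder on a block submatrix of raw dosages.

    ``val_index`` names held-out rows explicitly; otherwise a seeded
    random ``val_frac`` split is made.  The model trains only on the
    remaining rows, for exactly the recipe's epochs.
    """
    X = np.asarray(dosages, dtype=float)
    if X.shape[1] != spec.input_dim:
        raise ValueError(
            f"block {block_id}: {X.shape[1]} SNPs but spec.input_dim={spec.input_dim}"
        )
    if spec.input_dim == 1:
        warnings.warn(f"block {block_id} has a single SNP; pass-through candidate")
    n = X.shape[0]
    rng = np.random.default_rng(block_seed(recipe.seed, block_id))
    if val_index is None:
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_frac * n))) if n > 1 else 0
        val_index = perm[:n_val]
    val_mask = np.zeros(n, dtype=bool)
    val_mask[np.asarray(val_index, dtype=np.intp)] = True
    X_tr, X_val = X[~val_mask], X[val_mask]

    model = DenseAutoencoder(layer_widths(spec), seed=block_seed(recipe.seed, block_id),
                             leaky_slope=recipe.leaky_slope)
    history = model.fit(X_tr, recipe, shuffle_seed=block_seed(recipe.seed, block_id + ":shuffle"))

    rec_tr = model.reconstruct(X_tr)
    train_mse = float(np.mean((rec_tr - X_tr) ** 2))
    train_acc = snp_accuracy(rec_tr, X_tr).overall
    if X_val.shape[0]:
        rec_val = model.reconstruct(X_val)
        val_mse = float(np.mean((rec_val - X_val) ** 2))
        val_acc = snp_accuracy(rec_val, X_val).overall
    else:
        val_mse, val_acc = float("nan"), float("nan")
    return TrainedBlockModel(spec, model, block_id, train_mse, val_mse,
                             train_acc, val_acc, history)


def encode(m: TrainedBlockModel, dosages: np.ndarray) -> np.ndarray:
    """Bottleneck embedding (n_samples x bn) of a block submatrix."""
    X = np.asarray(dosages, dtype=float)
    if X.shape[1] != m.spec.input_dim:
        raise ValueError(
            f"block {m.block_id}: expected {m.spec.input_dim} columns, got {X.shape[1]}"
        )
    return m.model.encode(X)


def reconstruct(m: TrainedBlockModel, dosages: np.ndarray) -> np.ndarray:
    """Decoder output in (0, 2) for a block submatrix."""
    X = np.asarray(dosages, dtype=float)
    if X.shape[1] != m.spec.input_dim:
        raise ValueError(
            f"block {m.block_id}: expected {m.spec.input_dim} columns, got {X.shape[1]}"
        )
    return m.model.reconstruct(X)
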