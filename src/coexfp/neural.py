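"""Multilabel feedforward networks for pairwise co-annotation prediction.

A plain fully connected network maps a pair's per-dataset z-score vector to
one probability per predicted term.  Each term is an independent binary
classification task under a shared representation: the output layer emits one
logit per term, squashed by the logistic function, and training minimizes the
mean binary cross-entropy over terms and batch.  Minibatches are class
balanced — half drawn from related pairs, half from unrelated pairs — because
unrelated pairs outnumber related ones by orders of magnitude.  Optimization
is classical stochastic gradient descent with momentum, implemented directly
in numpy so training is exactly reproducible from the seeds alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class NetworkConfig:
    input_size: int
    output_size: int
    hidden_sizes: tuple[int, ...] = (500, 200, 100)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if min((self.input_size, self.output_size, *self.hidden_sizes)) < 1:
            raise ValueError("all layer sizes must be >= 1")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_size, *self.hidden_sizes, self.output_size)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 50
    positives_per_batch: int = 25
    learning_rate: float = 0.01
    momentum: float = 0.9
    iterations: int = 600_000
    seed: int = 0
    log_every: int = 1000

    def __post_init__(self) -> None:
        if self.positives_per_batch > self.batch_size:
            raise ValueError("positives_per_batch must be <= batch_size")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


class FeedforwardNetwork:
    """ReLU MLP with logistic outputs and scaled-uniform initialization.

    Every weight and bias of a layer is drawn i.i.d. from U[-k, k] with
    k = 1 / (that layer's input size).
    """

    def __init__(self, config: NetworkConfig, seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        sizes = config.layer_sizes
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            k = 1.0 / fan_in
            self.weights.append(rng.uniform(-k, k, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-k, k, size=fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_size:
            raise ValueError(
                f"expected input dimension {self.config.input_size}, got {X.shape[1]}"
            )
        return X

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Pre-squashing logits, one column per term."""
        A = self._check_input(X)
        for l in range(self.n_layers):
            Z = A @ self.weights[l] + self.biases[l]
            A = np.maximum(Z, 0.0) if l < self.n_layers - 1 else Z
        return A

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-pair, per-term scores in [0, 1]; no training side effects."""
        return expit(self.scores(X))

    def _forward_backward(self, X: np.ndarray, Y: np.ndarray):
        """Loss and parameter gradients for one batch."""
        X = self._check_input(X)
        Y = np.asarray(Y, dtype=float)
        acts = [X]
        pre: list[np.ndarray] = []
        A = X
        for l in range(self.n_layers):
            Z = A @ self.weights[l] + self.biases[l]
            pre.append(Z)
            A = np.maximum(Z, 0.0) if l < self.n_layers - 1 else Z
            acts.append(A)
        logits = pre[-1]
        loss = bce_loss(logits, Y)
        n = Y.size  # batch * terms: loss is a double mean
        delta = (expit(logits) - Y) / n
        grads_w = [np.empty(0)] * self.n_layers
        grads_b = [np.empty(0)] * self.n_layers
        for l in range(self.n_layers - 1, -1, -1):
            grads_w[l] = acts[l].T @ delta
            grads_b[l] = delta.sum(axis=0)
            if l > 0:
                delta = (delta @ self.weights[l].T) * (pre[l - 1] > 0)
        return loss, grads_w, grads_b

    def copy_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights] + [b.copy() for b in self.biases]


def init_network(config: NetworkConfig, seed: int = 0) -> FeedforwardNetwork:
    return FeedforwardNetwork(config, seed=seed)


def bce_loss(scores: np.ndarray, labels: np.ndarray, from_logits: bool = True) -> float:
    """Mean binary cross-entropy over terms and batch.

    With ``from_logits`` (the default) the numerically stable form
    max(z, 0) - z*y + log(1 + exp(-|z|)) is used, which never overflows even
    for saturated scores.
    """
    z = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if z.shape != y.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {y.shape}")
    if from_logits:
        per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    else:
        eps = 1e-12
        p = np.clip(z, eps, 1.0 - eps)
        per = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(np.mean(per))


def sample_minibatch(
    related: tuple[np.ndarray, np.ndarray],
    unrelated: tuple[np.ndarray, np.ndarray],
    tconfig: TrainingConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced minibatch, sampled uniformly with replacement per pool.

    ``related``/``unrelated`` are (features, labels) arrays; the batch stacks
    ``positives_per_batch`` related rows first, then the unrelated rows.
    """
    (Xr, Yr), (Xu, Yu) = related, unrelated
    if len(Xr) == 0 or len(Xu) == 0:
        raise ValueError("both pair pools must be non-empty")
    n_pos = tconfig.positives_per_batch
    n_neg = tconfig.batch_size - n_pos
    ri = rng.integers(0, len(Xr), size=n_pos)
    ui = rng.integers(0, len(Xu), size=n_neg)
    X = np.concatenate([Xr[ri], Xu[ui]], axis=0)
    Y = np.concatenate([Yr[ri], Yu[ui]], axis=0)
    return X, Y


@dataclass(eq=False)
class TrainedFold:
    """One fold's trained network plus its periodic training-loss trace."""

    fold_id: int
    network: FeedforwardNetwork
    loss_trace: np.ndarray  # (m, 2): iteration, minibatch loss
    network_config: NetworkConfig
    training_config: TrainingConfig
    init_seed: int


def train_fold(
    related: tuple[np.ndarray, np.ndarray],
    unrelated: tuple[np.ndarray, np.ndarray],
    nconfig: NetworkConfig,
    tconfig: TrainingConfig,
    fold_id: int = 0,
    init_seed: int | None = None,
) -> TrainedFold:
    """Run the balanced-minibatch SGD loop for a fixed iteration budget.

    Momentum is classical: v <- momentum*v + grad; w <- w - lr*v.  Minibatch
    sampling uses ``tconfig.seed``; weight initialization uses ``init_seed``
    (default ``tconfig.seed + 1``), so runs are bit-reproducible.
    """
    if init_seed is None:
        init_seed = tconfig.seed + 1
    net = FeedforwardNetwork(nconfig, seed=init_seed)
    rng = np.random.default_rng(tconfig.seed)
    vel_w = [np.zeros_like(w) for w in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    trace: list[tuple[int, float]] = []
    lr, mom = tconfig.learning_rate, tconfig.momentum
    for it in range(tconfig.iterations):
        X, Y = sample_minibatch(related, unrelated, tconfig, rng)
        loss, gw, gb = net._forward_backward(X, Y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"fold {fold_id}: non-finite loss at iteration {it}"
            )
        for l in range(net.n_layers):
            vel_w[l] = mom * vel_w[l] + gw[l]
            vel_b[l] = mom * vel_b[l] + gb[l]
            net.weights[l] -= lr * vel_w[l]
            net.biases[l] -= lr * vel_b[l]
        if it % tconfig.log_every == 0 or it == tconfig.iterations - 1:
            trace.append((it, loss))
    return TrainedFold(
        fold_id=fold_id,
        network=net,
        loss_trace=np.array(trace, dtype=float),
        network_config=nconfig,
        training_config=tconfig,
        init_seed=init_seed,
    )


def predict_pairs(fold: TrainedFold, features: np.ndarray) -> np.ndarray:
    """Batched per-pair, per-term scores in [0, 1] from a trained fold."""
    return fold.network.predict_proba(features)


# ---------------------------------------------------------------------------
# checkpoints (single-file npz: config + seeds + weights + loss trace)


def save_checkpoint(fold: TrainedFold, path: str | Path) -> None:
    meta = {
        "fold_id": fold.fold_id,
        "network_config": asdict(fold.network_config),
        "training_config": asdict(fold.training_config),
        "init_seed": fold.init_seed,
    }
    arrays = {
        f"w{l}": fold.network.weights[l] for l in range(fold.network.n_layers)
    }
    arrays.update(
        {f"b{l}": fold.network.biases[l] for l in range(fold.network.n_layers)}
    )
    np.savez(
        Path(path),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        loss_trace=fold.loss_trace,
        **arrays,
    )


def load_checkpoint(path: str | Path) -> TrainedFold:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        nconfig = NetworkConfig(
            input_size=meta["network_config"]["input_size"],
            output_size=meta["network_config"]["output_size"],
            hidden_sizes=tuple(meta["network_config"]["hidden_sizes"]),
        )
        tconfig = TrainingConfig(**meta["training_config"])
        net = FeedforwardNetwork(nconfig, seed=meta["init_seed"])
        for l in range(net.n_layers):
            net.weights[l] = data[f"w{l}"]
            net.biases[l] = data[f"b{l}"]
        return TrainedFold(
            fold_id=int(meta["fold_id"]),
            network=net,
            loss_trace=data["loss_trace"],
            network_config=nconfig,
            training_config=tconfig,
            init_seed=int(meta["init_seed"]),
        )


def write_loss_trace(fold: TrainedFold, path: str | Path, header_comment: str | None = None) -> None:
    with open(Path(path), "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("iteration\tloss\n")
        for it, loss in fold.loss_trace:
            fh.write(f"{int(it)}\t{loss:.6f}\n")
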