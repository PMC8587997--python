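"""Shallow fully connected network for step-cycle-to-participant matching.

One hidden layer with hyperbolic-tangent activation, sized at twice the
input dimensionality (10800 nodes for the full 5400-variable cycles), and
one linear output node per participant read out through a softmax.
Training is plain mini-batch gradient descent on the cross-entropy loss
(batches of 25, at most 1000 epochs), stopping early once the training set
has been classified perfectly at converged loss for 10 consecutive epochs.
Everything is seeded and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, SchemaError, TrainingDivergedError


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimization settings.

    ``hidden_nodes`` defaults to twice the input dimensionality.
    """

    input_nodes: int = 5400
    output_nodes: int = 20
    hidden_nodes: int | None = None
    batch_size: int = 25
    epoch_limit: int = 1000
    learning_rate: float = 0.05
    init_scale: float = 0.2
    early_stop_patience: int = 10
    early_stop_loss: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_nodes < 1 or self.output_nodes < 2:
            raise InvalidConfigError("need >= 1 input and >= 2 output nodes")
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning_rate must be positive")
        if self.epoch_limit < 0 or self.batch_size < 1:
            raise InvalidConfigError("invalid batch_size or epoch_limit")

    @property
    def resolved_hidden_nodes(self) -> int:
        return self.hidden_nodes if self.hidden_nodes is not None else 2 * self.input_nodes


@dataclass
class NetworkWeights:
    """Trained parameters of the 3-layer network."""

    w1: np.ndarray  # (input, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden, output)
    b2: np.ndarray  # (output,)
    classes: np.ndarray  # class labels in output-node order

    def save(self, path) -> None:
        classes = self.classes
        if classes.dtype == object:  # label strings from pandas
            classes = classes.astype(str)
        np.savez_compressed(path, w1=self.w1, b1=self.b1, w2=self.w2,
                            b2=self.b2, classes=classes)

    @classmethod
    def load(cls, path) -> "NetworkWeights":
        with np.load(path, allow_pickle=False) as data:
            return cls(w1=data["w1"], b1=data["b1"], w2=data["w2"],
                       b2=data["b2"], classes=data["classes"])


def _scaled_glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
                   scale: float) -> np.ndarray:
    limit = scale * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def initialize_weights(config: NetworkConfig, classes: np.ndarray) -> NetworkWeights:
    """Seeded uniform initialization on the Glorot scale, shrunk by
    ``init_scale`` so untrained connections start close to zero (which also
    keeps spurious relevance off untrained weights in later attribution)."""
    rng = np.random.default_rng([config.seed, 11])
    h = config.resolved_hidden_nodes
    return NetworkWeights(
        w1=_scaled_glorot(rng, config.input_nodes, h, config.init_scale),
        b1=np.zeros(h),
        w2=_scaled_glorot(rng, h, config.output_nodes, config.init_scale),
        b2=np.zeros(config.output_nodes),
        classes=np.asarray(classes),
    )


def forward(weights: NetworkWeights, x: np.ndarray):
    """Hidden activations and pre-softmax output scores for a batch."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != weights.w1.shape[0]:
        raise SchemaError(
            f"input has {x.shape[1]} columns, network expects {weights.w1.shape[0]}"
        )
    hidden = np.tanh(x @ weights.w1 + weights.b1)
    scores = hidden @ weights.w2 + weights.b2
    return hidden, scores


def _softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def sample_training_indices(participants: np.ndarray, per_participant: int,
                            seed: int) -> np.ndarray:
    """Seeded draw of ``per_participant`` cycle indices for every participant."""
    rng = np.random.default_rng([seed, 23])
    participants = np.asarray(participants)
    chosen = []
    for pid in pd.unique(participants):
        pool = np.flatnonzero(participants == pid)
        if pool.size < per_participant:
            raise InvalidConfigError(
                f"participant {pid} has only {pool.size} cycles, "
                f"needs {per_participant}"
            )
        chosen.append(rng.choice(pool, size=per_participant, replace=False))
    return np.sort(np.concatenate(chosen))


def train(x: np.ndarray, labels: np.ndarray, config: NetworkConfig
          ) -> tuple[NetworkWeights, dict]:
    """Train the network; returns weights and a training log.

    The log records per-epoch cross-entropy loss and training accuracy,
    whether early stopping fired, and the (assumed, since unconstrained by
    the architecture) softmax/cross-entropy readout used for optimization.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size != config.output_nodes:
        raise InvalidConfigError(
            f"{classes.size} distinct labels but {config.output_nodes} output nodes"
        )
    if x.shape[0] < 1:
        raise InvalidConfigError("empty training set")
    if config.batch_size > x.shape[0]:
        raise InvalidConfigError("batch_size exceeds training-set size")
    weights = initialize_weights(config, classes)
    rng = np.random.default_rng([config.seed, 29])
    n = x.shape[0]
    log = {"loss": [], "train_accuracy": [], "early_stopped": False,
           "epochs_run": 0, "loss_model": "softmax cross-entropy"}
    perfect_streak = 0
    for epoch in range(config.epoch_limit):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x[batch], y[batch]
            hidden, scores = forward(weights, xb)
            probs = _softmax(scores)
            grad_scores = probs
            grad_scores[np.arange(batch.size), yb] -= 1.0
            grad_scores /= batch.size
            grad_w2 = hidden.T @ grad_scores
            grad_b2 = grad_scores.sum(axis=0)
            grad_hidden = (grad_scores @ weights.w2.T) * (1.0 - hidden**2)
            grad_w1 = xb.T @ grad_hidden
            grad_b1 = grad_hidden.sum(axis=0)
            lr = config.learning_rate
            weights.w1 -= lr * grad_w1
            weights.b1 -= lr * grad_b1
            weights.w2 -= lr * grad_w2
            weights.b2 -= lr * grad_b2
        _, scores = forward(weights, x)
        probs = _softmax(scores)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-300).mean())
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}; "
                f"|w1|max={np.abs(weights.w1).max():.3g}"
            )
        acc = float((scores.argmax(axis=1) == y).mean())
        log["loss"].append(loss)
        log["train_accuracy"].append(acc)
        log["epochs_run"] = epoch + 1
        # stop only once the fit is genuinely converged: perfect training
        # accuracy alone still leaves the loss (and the weight structure
        # that later attribution depends on) far from its minimum
        converged = acc == 1.0 and loss <= config.early_stop_loss
        perfect_streak = perfect_streak + 1 if converged else 0
        if perfect_streak >= config.early_stop_patience:
            log["early_stopped"] = True
            break
    return weights, log


def classify(weights: NetworkWeights, x: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted participant label and pre-softmax scores per cycle.

    The prediction is the highest-scoring output node; exact ties resolve
    to the lowest class index.
    """
    _, scores = forward(weights, x)
    pred = weights.classes[scores.argmax(axis=1)]
    return pred, scores


@dataclass
class AccuracyReport:
    """Per-participant and overall identification accuracy in percent."""

    per_participant: pd.DataFrame  # participant, n_correct, n_total, accuracy
    overall: float

    def __str__(self) -> str:
        return (
            f"overall accuracy {self.overall:.2f}% over "
            f"{int(self.per_participant['n_total'].sum())} cycles"
        )


def accuracy_by_participant(predictions: np.ndarray, labels: np.ndarray
                            ) -> AccuracyReport:
    """Accuracy(p) = n_correct(p) / n_total(p) * 100, plus the overall ratio.

    Labels never seen among the true labels but present in predictions are
    counted as incorrect (with a warning); a participant absent from the
    test set is reported with missing accuracy rather than zero.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise SchemaError("predictions and labels differ in length")
    unseen = set(np.unique(predictions)) - set(np.unique(labels))
    if unseen:
        warnings.warn(f"predictions contain labels never present in truth: {unseen}")
    rows = []
    for pid in pd.unique(labels):
        sel = labels == pid
        n_total = int(sel.sum())
        n_correct = int((predictions[sel] == pid).sum())
        acc = n_correct / n_total * 100.0 if n_total else np.nan
        rows.append((pid, n_correct, n_total, acc))
    frame = pd.DataFrame(rows, columns=["participant", "n_correct", "n_total",
                                        "accuracy"])
    overall = float(frame["n_correct"].sum() / frame["n_total"].sum() * 100.0)
    return AccuracyReport(per_participant=frame, overall=overall)
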