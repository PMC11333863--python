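"""Optimization of the dual-stream classifier.

Cross-entropy loss, Adam, step learning-rate decay, best-checkpoint
selection by validation F1, and random hyperparameter search over the
batch-size x learning-rate grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .model.layers import DTYPE, cross_entropy
from .model.network import DualStreamNet, ModelConfig
from .types import FALL, SensorSegment

BATCH_SIZE_CHOICES = (32, 64, 128)
LEARNING_RATE_CHOICES = (0.001, 0.005, 0.01)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``max_epochs`` counts full passes over the training set; set
    ``epoch_unit='step'`` to interpret it as optimizer steps instead.
    ``lr_decay_epochs`` lists epochs at which the learning rate is
    multiplied by ``lr_decay_factor`` (gradual decrease from the initial
    rate).
    """

    max_epochs: int = 300
    batch_size: int = 128
    initial_lr: float = 0.001
    lr_decay_epochs: Tuple[int, ...] = (100, 200)
    lr_decay_factor: float = 0.1
    epoch_unit: str = "epoch"  # 'epoch' | 'step'
    seed: int = 0
    class_weighting: bool = False
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.max_epochs <= 0 or self.batch_size <= 0 or self.initial_lr <= 0:
            raise ValueError("max_epochs, batch_size and initial_lr must be positive")
        if self.epoch_unit not in ("epoch", "step"):
            raise ValueError("epoch_unit must be 'epoch' or 'step'")

    def lr_at(self, epoch: int) -> float:
        lr = self.initial_lr
        for boundary in self.lr_decay_epochs:
            if epoch >= boundary:
                lr *= self.lr_decay_factor
        return lr


@dataclass
class TrainHistory:
    """Per-epoch learning curves."""

    train_loss: List[float] = field(default_factory=list)
    valid_loss: List[float] = field(default_factory=list)
    valid_f1: List[float] = field(default_factory=list)
    best_epoch: int = -1

    def as_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "valid_loss": self.valid_loss,
            "valid_f1": self.valid_f1,
            "best_epoch": self.best_epoch,
        }


class Adam:
    """Adam optimizer over a named-parameter dict."""

    def __init__(self, params: Dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for key, p in self.params.items():
            g = grads[key].astype(p.dtype)
            if not np.isfinite(g).all():
                raise FloatingPointError(f"non-finite gradient for {key}")
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / bias1
            vhat = self.v[key] / bias2
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def segments_to_arrays(
    segments: Sequence[SensorSegment],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack segments into (acc, gyro, labels, subjects) batch arrays."""
    if not segments:
        raise ValueError("no segments provided")
    los = segments[0].los
    if any(s.los != los for s in segments):
        raise ValueError("segments have mixed lengths")
    acc = np.stack([s.acc for s in segments]).astype(DTYPE)
    gyro = np.stack([s.gyro for s in segments]).astype(DTYPE)
    labels = np.array([1 if s.label == FALL else 0 for s in segments])
    subjects = np.array([s.subject_id for s in segments])
    return acc, gyro, labels, subjects


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def _eval_loss_f1(net: DualStreamNet, acc, gyro, labels, batch: int = 256) -> Tuple[float, float]:
    losses, preds = [], []
    for i in range(0, len(labels), batch):
        logits = net.logits(acc[i : i + batch], gyro[i : i + batch], train=False)
        loss, _ = cross_entropy(logits, labels[i : i + batch])
        losses.append(loss * (min(i + batch, len(labels)) - i))
        preds.append(logits.argmax(axis=1))
    preds = np.concatenate(preds)
    return float(np.sum(losses) / len(labels)), _binary_f1(labels, preds)


def train(
    model_init: DualStreamNet | ModelConfig,
    train_segments: Sequence[SensorSegment],
    valid_segments: Sequence[SensorSegment],
    config: TrainConfig = TrainConfig(),
) -> Tuple[DualStreamNet, TrainHistory]:
    """Fit the network on labeled segments; returns the best-validation-F1
    checkpoint and the learning curves.

    Training and validation sets are expected to be subject-disjoint; the
    training set must contain both classes. Deterministic given
    ``config.seed`` (shuffling and dropout both derive from it).
    """
    acc_t, gyro_t, y_t, subj_t = segments_to_arrays(train_segments)
    acc_v, gyro_v, y_v, subj_v = segments_to_arrays(valid_segments)
    if len(set(subj_t) & set(subj_v)) > 0:
        raise ValueError("train and validation sets share subjects")
    if len(np.unique(y_t)) < 2:
        raise ValueError("training set must contain both fall and ADL segments")

    if isinstance(model_init, ModelConfig):
        net = DualStreamNet(replace(model_init, seed=config.seed))
    else:
        net = model_init
    # input standardization from training statistics
    mean = np.concatenate([acc_t.reshape(-1, 3).mean(0), gyro_t.reshape(-1, 3).mean(0)])
    std = np.concatenate([acc_t.reshape(-1, 3).std(0), gyro_t.reshape(-1, 3).std(0)])
    net.set_normalization(mean, std)
    net.dropout.rng = np.random.default_rng(config.seed + 7919)

    params = net.parameters()
    optimizer = Adam(params)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    n = len(y_t)
    steps_per_epoch = math.ceil(n / config.batch_size)
    max_epochs = (
        config.max_epochs
        if config.epoch_unit == "epoch"
        else math.ceil(config.max_epochs / steps_per_epoch)
    )
    if config.class_weighting:
        counts = np.bincount(y_t, minlength=2)
        class_w = (n / (2.0 * np.maximum(counts, 1))).astype(DTYPE)
    else:
        class_w = None

    best_f1 = -1.0
    best_state = net.state_dict()
    for epoch in range(max_epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = net.logits(acc_t[idx], gyro_t[idx], train=True)
            loss, dlogits = cross_entropy(logits, y_t[idx])
            if class_w is not None:
                w = class_w[y_t[idx]][:, None]
                dlogits = dlogits * w
                loss = float(loss)  # reported loss stays unweighted
            if not math.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            net.backward(dlogits.astype(DTYPE))
            optimizer.step(net.gradients(), lr)
            epoch_loss += loss * len(idx)
        v_loss, v_f1 = _eval_loss_f1(net, acc_v, gyro_v, y_v)
        history.train_loss.append(epoch_loss / n)
        history.valid_loss.append(v_loss)
        history.valid_f1.append(v_f1)
        if v_f1 > best_f1:
            best_f1 = v_f1
            best_state = net.state_dict()
            history.best_epoch = epoch
    net.load_state_dict(best_state)
    return net, history


def split_validation_subjects(
    subjects: Sequence[str], fraction: float = 0.1, seed: int = 0
) -> Tuple[List[str], List[str]]:
    """Hold out ~``fraction`` of training subjects (at least one) for model
    selection; returns (fit_subjects, validation_subjects)."""
    subjects = list(dict.fromkeys(subjects))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to form a validation split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_valid = max(1, int(round(fraction * len(subjects))))
    n_valid = min(n_valid, len(subjects) - 1)
    valid = sorted(subjects[i] for i in order[:n_valid])
    fit = sorted(subjects[i] for i in order[n_valid:])
    return fit, valid


@dataclass(frozen=True)
class SearchSpace:
    batch_sizes: Tuple[int, ...] = BATCH_SIZE_CHOICES
    learning_rates: Tuple[float, ...] = LEARNING_RATE_CHOICES


def random_search(
    space: SearchSpace,
    n_draws: int,
    base_config: TrainConfig,
    train_segments: Sequence[SensorSegment],
    valid_segments: Sequence[SensorSegment],
    seed: int = 0,
    model_config: ModelConfig = ModelConfig(),
) -> Tuple[TrainConfig, List[Tuple[TrainConfig, float]]]:
    """Random search over batch-size x learning-rate combinations.

    Draws uniformly without replacement while ``n_draws`` does not exceed
    the grid size (so an exhaustive budget evaluates every combination
    exactly once); each draw is trained with ``base_config``'s schedule and
    ranked by best validation F1. Returns the winning config and the full
    (config, F1) ranking.
    """
    grid = list(itertools.product(space.batch_sizes, space.learning_rates))
    if not grid:
        raise ValueError("empty search space")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    if n_draws <= len(grid):
        picks = [grid[i] for i in rng.choice(len(grid), size=n_draws, replace=False)]
    else:
        picks = [grid[i] for i in rng.integers(0, len(grid), size=n_draws)]
    results: List[Tuple[TrainConfig, float]] = []
    for batch_size, lr in picks:
        cfg = replace(base_config, batch_size=int(batch_size), initial_lr=float(lr))
        _, history = train(model_config, train_segments, valid_segments, cfg)
        results.append((cfg, max(history.valid_f1)))
    results.sort(key=lambda item: -item[1])
    return results[0][0], results
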