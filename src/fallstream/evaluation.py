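"""Detection metrics and the evaluation studies built on them.

Covers confusion-matrix metrics (fall = positive class), subject-wise
k-fold cross-validation, the sampling-rate ablation, pre/post-attention
embedding export (for t-SNE-style inspection) and the sliding-window
streaming detector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd

from .model.network import DualStreamNet, ModelConfig
from .preprocess import filter_segments, lowpass_filter, resample_to, subject_folds, subject_split
from .training import (
    TrainConfig,
    segments_to_arrays,
    split_validation_subjects,
    train,
)
from .types import ADL, FALL, Confusion, EvalReport, SensorSegment

logger = logging.getLogger(__name__)


def compute_metrics(c: Confusion) -> EvalReport:
    """Accuracy, recall, precision, specificity and F1 (percent) from counts.

    * accuracy    = (TP + TN) / total
    * recall      = TP / (TP + FN)        (fall-detection sensitivity)
    * precision   = TP / (TP + FP)
    * specificity = TN / (TN + FP)        (ADL correctly kept silent)
    * F1          = 2 * precision * recall / (precision + recall)

    A zero denominator makes the metric 0 and adds its name to
    ``undefined`` instead of raising.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion matrix")
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return 0.0
        return 100.0 * num / den

    accuracy = 100.0 * (c.tp + c.tn) / c.total
    recall = ratio(c.tp, c.tp + c.fn, "recall")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    if precision + recall == 0:
        undefined.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalReport(
        accuracy=accuracy, recall=recall, precision=precision,
        specificity=specificity, f1=f1, confusion=c, undefined=frozenset(undefined),
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2 * precision * recall / (precision + recall), on the percent scale."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be nonnegative")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> Confusion:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return Confusion(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def evaluate(net: DualStreamNet, segments: Sequence[SensorSegment], batch: int = 256) -> EvalReport:
    """Eval-mode forward passes over ``segments`` -> metrics report."""
    if not segments:
        raise ValueError("no segments to evaluate")
    acc, gyro, labels, _ = segments_to_arrays(segments)
    preds = []
    for i in range(0, len(labels), batch):
        preds.append(net.predict(acc[i : i + batch], gyro[i : i + batch]))
    return compute_metrics(confusion_from_predictions(labels, np.concatenate(preds)))


def train_and_evaluate(
    segments: Sequence[SensorSegment],
    train_subjects: Sequence[str],
    test_subjects: Sequence[str],
    config: TrainConfig,
    model_config: ModelConfig = ModelConfig(),
    valid_fraction: float = 0.1,
) -> Tuple[DualStreamNet, EvalReport]:
    """Train on ``train_subjects`` (with an internal subject-wise validation
    holdout for checkpoint selection) and report metrics on ``test_subjects``."""
    fit_subj, valid_subj = split_validation_subjects(
        train_subjects, valid_fraction, config.seed
    )
    net, _ = train(
        model_config,
        filter_segments(segments, fit_subj),
        filter_segments(segments, valid_subj),
        config,
    )
    return net, evaluate(net, filter_segments(segments, test_subjects))


def cross_validate(
    segments: Sequence[SensorSegment],
    k: int,
    config: TrainConfig,
    seed: int = 0,
    model_config: ModelConfig = ModelConfig(),
) -> Tuple[List[float], float]:
    """Subject-wise k-fold cross-validation; returns (per-fold F1 %, mean).

    Subjects are shuffled once (deterministic given ``seed``) and split
    into ``k`` near-equal folds; each fold serves as the test group while
    the others train a fresh model.
    """
    subjects = list(dict.fromkeys(s.subject_id for s in segments))
    folds = subject_folds(subjects, k, seed)
    f1s: List[float] = []
    for i, test_subj in enumerate(folds):
        train_subj = [s for s in subjects if s not in set(test_subj)]
        cfg = replace(config, seed=config.seed + i)
        _, report = train_and_evaluate(segments, train_subj, test_subj, cfg, model_config)
        f1s.append(report.f1)
    return f1s, float(np.mean(f1s))


def mean_fold_f1(fold_f1s: Sequence[float]) -> float:
    """Arithmetic mean of per-fold F1 scores (the tabulated 'Average')."""
    if not fold_f1s:
        raise ValueError("no fold scores")
    return float(np.mean(fold_f1s))


def resample_segment(seg: SensorSegment, rate: float) -> SensorSegment:
    """Re-resample one segment to a lower rate with anti-alias filtering."""
    if rate > seg.fs:
        raise ValueError(f"target rate {rate} exceeds segment rate {seg.fs}")
    if rate == seg.fs:
        return seg
    cutoff = 0.4 * rate
    acc = resample_to(lowpass_filter(seg.acc, seg.fs, cutoff), seg.fs, rate)
    gyro = resample_to(lowpass_filter(seg.gyro, seg.fs, cutoff), seg.fs, rate)
    return SensorSegment(acc=acc, gyro=gyro, fs=rate, label=seg.label, subject_id=seg.subject_id)


def sampling_rate_ablation(
    segments: Sequence[SensorSegment],
    rates: Sequence[float] = (50.0, 10.0, 5.0),
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    model_config: ModelConfig = ModelConfig(),
    split_ratio: float = 0.8,
) -> Dict[float, EvalReport]:
    """Retrain and evaluate one model per sampling rate.

    Each rate gets its own from-scratch training run on re-resampled
    segments (shared seed and subject split), mirroring a per-rate model
    comparison rather than evaluating one model on degraded input. A 12 s
    window becomes 120 samples at 10 Hz and 60 at 5 Hz.
    """
    base_fs = segments[0].fs
    for rate in rates:
        if rate > base_fs:
            raise ValueError(f"rate {rate} Hz exceeds base rate {base_fs} Hz")
    split = subject_split([s.subject_id for s in segments], split_ratio, seed)
    results: Dict[float, EvalReport] = {}
    for rate in rates:
        resampled = [resample_segment(s, rate) for s in segments]
        cfg = replace(config, seed=seed)
        _, report = train_and_evaluate(
            resampled, split.train_subjects, split.test_subjects, cfg, model_config
        )
        results[float(rate)] = report
    return results


def export_embeddings(
    net: DualStreamNet, segments: Sequence[SensorSegment], batch: int = 256
) -> pd.DataFrame:
    """Pre- and post-attention 64-D feature vectors, one row per segment per
    stream.

    Columns: ``stream`` ('acc'/'gyro'), ``label``, ``subject_id``,
    ``pre_00..pre_63``, ``post_00..post_63``. The table is what a t-SNE /
    silhouette analysis of the attention module's effect consumes.
    """
    if not segments:
        raise ValueError("no segments provided")
    acc, gyro, labels, subjects = segments_to_arrays(segments)
    rows = {"acc": {"pre": [], "post": []}, "gyro": {"pre": [], "post": []}}
    for i in range(0, len(labels), batch):
        _, diag = net.forward(acc[i : i + batch], gyro[i : i + batch], train=False)
        for stream in ("acc", "gyro"):
            rows[stream]["pre"].append(diag.pre_attention[stream])
            rows[stream]["post"].append(diag.post_attention[stream].weighted)
    frames = []
    dim = net.config.feature_dim
    for stream in ("acc", "gyro"):
        pre = np.concatenate(rows[stream]["pre"])
        post = np.concatenate(rows[stream]["post"])
        meta = pd.DataFrame(
            {
                "stream": stream,
                "label": [FALL if y else ADL for y in labels],
                "subject_id": subjects,
            }
        )
        pre_df = pd.DataFrame(pre, columns=[f"pre_{j:02d}" for j in range(dim)])
        post_df = pd.DataFrame(post, columns=[f"post_{j:02d}" for j in range(dim)])
        frames.append(pd.concat([meta, pre_df, post_df], axis=1))
    return pd.concat(frames, ignore_index=True)


def silhouette_pre_post(embeddings: pd.DataFrame) -> Tuple[float, float]:
    """Silhouette score of fall-vs-ADL separation before and after attention.

    Features from both streams are concatenated per segment (128-D pre,
    128-D post). Higher post-attention silhouette means the attention
    re-weighting increased class separation.
    """
    from sklearn.metrics import silhouette_score

    pre_cols = [c for c in embeddings.columns if c.startswith("pre_")]
    post_cols = [c for c in embeddings.columns if c.startswith("post_")]
    acc = embeddings[embeddings["stream"] == "acc"].reset_index(drop=True)
    gyro = embeddings[embeddings["stream"] == "gyro"].reset_index(drop=True)
    labels = (acc["label"] == FALL).to_numpy().astype(int)
    pre = np.hstack([acc[pre_cols].to_numpy(), gyro[pre_cols].to_numpy()])
    post = np.hstack([acc[post_cols].to_numpy(), gyro[post_cols].to_numpy()])
    return (
        float(silhouette_score(pre, labels)),
        float(silhouette_score(post, labels)),
    )


class StreamPrediction(NamedTuple):
    time: float  # seconds; right edge of the window
    label: str  # FALL or ADL
    probability: float  # probability of fall


def sliding_window_predict(
    acc: np.ndarray,
    gyro: np.ndarray,
    net: DualStreamNet,
    fs: float = 50.0,
    window_s: float = 8.0,
    hop_s: float = 0.5,
) -> List[StreamPrediction]:
    """On-line inference over a continuous 50 Hz stream.

    Every ``hop_s`` seconds the most recent ``window_s`` of data is
    classified; the first prediction is available at ``t = window_s``. Any
    window labeled fall is an alarm event (no debouncing). A stream
    shorter than one window yields an empty list with a warning.
    """
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    los = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    n = min(acc.shape[0], gyro.shape[0])
    if n < los:
        warnings.warn(
            f"stream of {n} samples is shorter than one {window_s}s window; no predictions",
            stacklevel=2,
        )
        return []
    starts = np.arange(0, n - los + 1, hop)
    acc_w = np.stack([acc[s : s + los] for s in starts])
    gyro_w = np.stack([gyro[s : s + los] for s in starts])
    out: List[StreamPrediction] = []
    batch = 256
    for i in range(0, len(starts), batch):
        probs, _ = net.forward(acc_w[i : i + batch], gyro_w[i : i + batch], train=False)
        for j, p in enumerate(probs):
            t = (starts[i + j] + los) / fs
            label = FALL if p[1] >= p[0] else ADL
            out.append(StreamPrediction(time=float(t), label=label, probability=float(p[1])))
    return out


def alarms(predictions: Sequence[StreamPrediction]) -> List[StreamPrediction]:
    """Windows flagged as falls (alarm events)."""
    return [p for p in predictions if p.label == FALL]
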