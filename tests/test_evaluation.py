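"""Metrics, cross-validation, ablation, embeddings and streaming inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallstream.evaluation import (
    compute_metrics,
    confusion_from_predictions,
    cross_validate,
    evaluate,
    export_embeddings,
    f1_from_precision_recall,
    mean_fold_f1,
    resample_segment,
    sliding_window_predict,
)
from fallstream.model.network import DualStreamNet, ModelConfig
from fallstream.preprocess import segment_cohort
from fallstream.synth import generate_cohort, generate_stream
from fallstream.training import TrainConfig
from fallstream.types import ADL, FALL, Confusion, SensorSegment


# ---------------------------------------------------------------- metrics
def test_metrics_from_reconstructed_confusion():
    """Counts consistent with a 1183-segment test set, 5 false positives
    and 3 false negatives reproduce the printed accuracy/recall/precision."""
    report = compute_metrics(Confusion(tp=350, fn=3, fp=5, tn=825))
    assert report.accuracy == pytest.approx(99.32, abs=0.01)
    assert report.recall == pytest.approx(99.15, abs=0.01)
    assert report.precision == pytest.approx(98.59, abs=0.01)


def test_perfect_classifier_all_metrics_100():
    report = compute_metrics(Confusion(tp=10, fn=0, fp=0, tn=20))
    for value in (report.accuracy, report.recall, report.precision,
                  report.specificity, report.f1):
        assert value == 100.0
    assert not report.undefined


def test_f1_from_printed_precision_recall():
    assert f1_from_precision_recall(98.39, 100.0) == pytest.approx(99.19, abs=0.01)
    assert f1_from_precision_recall(0.0, 0.0) == 0.0


def test_undefined_ratios_flagged_not_raised():
    report = compute_metrics(Confusion(tp=0, fn=0, fp=0, tn=5))
    assert report.recall == 0.0 and report.f1 == 0.0
    assert {"recall", "f1"} <= set(report.undefined)
    with pytest.raises(ValueError):
        compute_metrics(Confusion(tp=0, fn=0, fp=0, tn=0))


def test_metric_identities_on_1000_random_confusions():
    """Property suite: formula identities against an independent evaluation
    via expanded prediction arrays and scikit-learn."""
    from sklearn.metrics import f1_score, precision_score, recall_score

    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(1000, 4))
    for tp, fn, fp, tn in counts:
        if tp + fn + fp + tn == 0:
            continue
        c = Confusion(int(tp), int(fn), int(fp), int(tn))
        r = compute_metrics(c)
        assert r.accuracy * c.total == pytest.approx(100 * (c.tp + c.tn), abs=1e-6)
        if r.precision + r.recall > 0:
            assert r.f1 == pytest.approx(
                2 * r.precision * r.recall / (r.precision + r.recall), abs=1e-9
            )
        y_true = np.concatenate([np.ones(tp + fn), np.zeros(fp + tn)])
        y_pred = np.concatenate([np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)])
        if tp + fn and tp + fp:
            assert r.recall == pytest.approx(100 * recall_score(y_true, y_pred), abs=1e-9)
            assert r.precision == pytest.approx(100 * precision_score(y_true, y_pred), abs=1e-9)
            assert r.f1 == pytest.approx(100 * f1_score(y_true, y_pred), abs=1e-6)
        back = confusion_from_predictions(y_true, y_pred)
        assert back == c


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500))
def test_metrics_bounded_property(tp, fn, fp, tn):
    r = compute_metrics(Confusion(tp, fn, fp, tn))
    for v in (r.accuracy, r.recall, r.precision, r.specificity, r.f1):
        assert 0.0 <= v <= 100.0


def test_fold_averages_match_printed_tables():
    """Arithmetic fold means reproduce the tabulated cross-validation
    averages (2-dp rounding tolerance)."""
    assert mean_fold_f1([99.29, 99.01, 99.57, 98.86, 98.72]) == pytest.approx(99.09, abs=0.005)
    assert mean_fold_f1([99.19, 98.36, 98.33, 98.39, 99.17]) == pytest.approx(98.69, abs=0.005)
    assert mean_fold_f1([5 * [97.5]][0]) == 97.5
    with pytest.raises(ValueError):
        mean_fold_f1([])


# --------------------------------------------------------------- evaluate
def _constant_net(always: int) -> DualStreamNet:
    net = DualStreamNet(ModelConfig(seed=0))
    net.fc2.params["W"][:] = 0
    net.fc2.params["b"][:] = 0
    net.fc2.params["b"][always] = 10.0
    return net


def _segments(n_fall, n_adl, los=120, fs=10.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_fall + n_adl):
        label = FALL if i < n_fall else ADL
        out.append(
            SensorSegment(rng.normal(size=(los, 3)), rng.normal(size=(los, 3)), fs, label, f"S{i % 3}")
        )
    return out


def test_always_fall_model_recall_100_specificity_0():
    report = evaluate(_constant_net(1), _segments(5, 7))
    assert report.recall == 100.0
    assert report.specificity == 0.0
    report_adl = evaluate(_constant_net(0), _segments(5, 7))
    assert report_adl.recall == 0.0 and report_adl.specificity == 100.0


def test_evaluate_empty_rejected():
    with pytest.raises(ValueError):
        evaluate(_constant_net(0), [])


def test_random_guess_accuracy_near_half():
    """An untrained net behaves like a (deterministic) guesser: on a
    balanced set its accuracy cannot stray far from 50% unless inputs are
    informative; random inputs give ~50% within a binomial bound."""
    net = DualStreamNet(ModelConfig(seed=123))
    segs = _segments(500, 500, seed=9)
    report = evaluate(net, segs)
    assert 40.0 <= report.accuracy <= 60.0


# ----------------------------------------------------- cross-validation
def test_cross_validate_subject_wise():
    cohort = generate_cohort(5, 3, 3, fs=50.0, seed=21)
    segments = [
        resample_segment(s, 10.0) for s in segment_cohort(cohort.trials, 12.0, 50.0)
    ]
    cfg = TrainConfig(max_epochs=3, batch_size=16, seed=1)
    f1s, mean = cross_validate(segments, k=5, config=cfg, seed=1)
    assert len(f1s) == 5
    assert mean == pytest.approx(np.mean(f1s))
    with pytest.raises(ValueError):
        cross_validate(segments, k=6, config=cfg, seed=1)


# ----------------------------------------------------------- embeddings
def test_export_embeddings_shape_and_recomputation(trained_model, default_segments):
    net, _ = trained_model
    segs = default_segments[:40]
    table = export_embeddings(net, segs)
    assert len(table) == 2 * len(segs)
    assert set(table["stream"]) == {"acc", "gyro"}
    pre_cols = [c for c in table.columns if c.startswith("pre_")]
    post_cols = [c for c in table.columns if c.startswith("post_")]
    assert len(pre_cols) == len(post_cols) == 64

    # post-attention vectors equal A @ v recomputed from diagnostics
    from fallstream.training import segments_to_arrays

    acc, gyro, _, _ = segments_to_arrays(segs)
    _, diag = net.forward(acc, gyro)
    out = diag.post_attention["acc"]
    x = diag.pre_attention["acc"]
    v = x @ net.acc_stream.attn.params["Wv"].T
    recomputed = np.einsum("nij,nj->ni", out.attention, v)
    np.testing.assert_allclose(recomputed, out.weighted, atol=1e-4)
    table_acc = table[table["stream"] == "acc"][post_cols].to_numpy()
    np.testing.assert_allclose(table_acc, out.weighted, atol=1e-5)


# ------------------------------------------------------------- streaming
def test_sliding_window_prediction_count(streaming_model):
    net, _ = streaming_model
    rec = generate_stream(50.0, 60.0, seed=5)
    preds = sliding_window_predict(rec.acc, rec.gyro, net, fs=50.0, window_s=8.0, hop_s=0.5)
    assert len(preds) == 105  # floor((60 - 8) / 0.5) + 1
    assert preds[0].time == pytest.approx(8.0)
    assert preds[-1].time == pytest.approx(60.0)


def test_short_stream_warns_and_returns_empty(streaming_model):
    net, _ = streaming_model
    rec = generate_stream(50.0, 60.0, seed=5)
    with pytest.warns(UserWarning, match="shorter"):
        preds = sliding_window_predict(rec.acc[:100], rec.gyro[:100], net, fs=50.0)
    assert preds == []


def test_resample_segment_rejects_upsampling(default_segments):
    with pytest.raises(ValueError):
        resample_segment(default_segments[0], 100.0)
    seg10 = resample_segment(default_segments[0], 10.0)
    assert seg10.los == 120 and seg10.fs == 10.0
    seg5 = resample_segment(default_segments[0], 5.0)
    assert seg5.los == 60
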