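import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recspot.classifier import COLDSPOT, HOTSPOT
from recspot.evaluation import ConfusionCounts, MetricSet, jackknife, kfold, metrics


def miss_count_metrics(counts):
    """Independent oracle: the miss-count (N-+, N+-) formulation."""
    n_pos, n_neg = counts.n_pos, counts.n_neg
    return (
        1 - counts.fn / n_pos,
        1 - counts.fp / n_neg,
        1 - (counts.fn + counts.fp) / (n_pos + n_neg),
    )


def test_counts_identities():
    c = ConfusionCounts(tp=9, tn=8, fp=2, fn=1)
    assert c.n_pos == c.tp + c.fn == 10
    assert c.n_neg == c.tn + c.fp == 10
    assert c.n_pos_as_neg == c.fn
    assert c.n_neg_as_pos == c.fp


def test_counts_from_labels():
    y_true = [HOTSPOT, HOTSPOT, COLDSPOT, COLDSPOT, HOTSPOT]
    y_pred = [HOTSPOT, COLDSPOT, COLDSPOT, HOTSPOT, HOTSPOT]
    assert ConfusionCounts.from_labels(y_true, y_pred) == ConfusionCounts(
        tp=2, tn=1, fp=1, fn=1
    )


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


def test_perfect_sensitivity_when_no_hotspot_is_missed():
    m = metrics(ConfusionCounts(tp=7, tn=5, fp=3, fn=0))
    assert m.sn == 1.0


def test_half_errors_give_chance_level_metrics():
    # N-+ = N+/2 and N+- = N-/2: no better than random guessing
    m = metrics(ConfusionCounts(tp=5, fn=5, tn=6, fp=6))
    assert m.acc == 0.5
    assert m.mcc == 0.0


def test_worked_confusion_table():
    m = metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
    assert m.sn == pytest.approx(0.9)
    assert m.sp == pytest.approx(0.8)
    assert m.acc == pytest.approx(0.85)
    assert m.mcc == pytest.approx(70 / math.sqrt(9900))


def test_undefined_mcc_is_zero_and_flagged():
    m = metrics(ConfusionCounts(tp=0, fn=3, tn=4, fp=0))  # TP+FP == 0
    assert m.mcc == 0.0 and not m.mcc_defined


def test_metrics_require_both_classes():
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(tp=3, fn=1, tn=0, fp=0))


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    st.integers(1, 12), st.integers(1, 12), st.integers(0, 12), st.integers(0, 12)
)
def test_ratio_and_miss_count_formulations_agree(tp, tn, fn_extra, fp_extra):
    c = ConfusionCounts(tp=tp, tn=tn, fn=fn_extra, fp=fp_extra)
    m = metrics(c)
    sn, sp, acc = miss_count_metrics(c)
    assert m.sn == pytest.approx(sn, abs=1e-12)
    assert m.sp == pytest.approx(sp, abs=1e-12)
    assert m.acc == pytest.approx(acc, abs=1e-12)
    assert -1 <= m.mcc <= 1


@settings(derandomize=True, max_examples=150, deadline=None)
@given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
def test_mcc_sign_flips_under_label_inversion(tp, tn, fp, fn):
    if tp + fn == 0 or tn + fp == 0:
        return
    m = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    # inverting predictions swaps TP<->FN and TN<->FP
    inv = metrics(ConfusionCounts(tp=fn, tn=fp, fp=tn, fn=tp))
    assert inv.mcc == pytest.approx(-m.mcc, abs=1e-12)


def test_jackknife_on_separable_clusters_is_perfect(blob_dataset):
    X, y = blob_dataset
    result = jackknife(X, y)
    assert result.metrics.acc == 1.0
    assert (result.predictions["error"] == "").all()


def test_jackknife_on_permuted_labels_is_near_chance(blob_dataset):
    X, y = blob_dataset
    y_perm = np.random.default_rng(11).permutation(y)
    result = jackknife(X, y_perm)
    assert 0.2 <= result.metrics.acc <= 0.8


def test_jackknife_surfaces_single_class_folds_per_sample():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(3, 69))
    y = np.array([HOTSPOT, COLDSPOT, COLDSPOT])
    result = jackknife(X, y)
    # leaving out the singleton hotspot leaves a single-class training fold
    row = result.predictions.iloc[0]
    assert "single class" in row["error"]
    assert (result.predictions["error"].iloc[1:] == "").all()
    # with no evaluated hotspot left, the aggregate metric set is undefined
    assert result.metrics is None


def test_kfold_with_n_folds_equals_jackknife(blob_dataset):
    X, y = blob_dataset
    assert kfold(X, y, folds=len(y)).counts == jackknife(X, y).counts


def test_kfold_is_deterministic_per_seed_and_accurate(blob_dataset):
    X, y = blob_dataset
    a = kfold(X, y, folds=5, seed=3)
    b = kfold(X, y, folds=5, seed=3)
    assert a.metrics == b.metrics
    assert a.metrics.acc >= 0.95


def test_kfold_bounds(blob_dataset):
    X, y = blob_dataset
    with pytest.raises(ValueError):
        kfold(X, y, folds=len(y) + 1)
    with pytest.raises(ValueError):
        kfold(X, y, folds=1)


def test_report_serialization(blob_dataset, tmp_path):
    X, y = blob_dataset
    result = kfold(X, y, folds=4)
    result.to_json(tmp_path / "report.json")
    result.predictions_to_tsv(tmp_path / "pred.tsv")
    import json

    payload = json.loads((tmp_path / "report.json").read_text())
    assert payload["metrics"]["acc"] == result.metrics.acc
    assert payload["counts"]["tp"] == result.counts.tp
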