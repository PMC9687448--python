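"""Confusion metrics, frame agreement, grouped folds, observer statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octovessel import evaluate as ev


def brute_metrics(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else math.nan,
        "specificity": tn / (tn + fp) if tn + fp else math.nan,
        "accuracy": (tp + tn) / total,
        "dice": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else math.nan,
    }


def test_confusion_trivial_cases(rng):
    truth = rng.random((20, 20)) > 0.5
    same = ev.confusion(truth, truth)
    assert same.fp == same.fn == 0
    flipped = ev.confusion(~truth, truth)
    assert flipped.tp == flipped.tn == 0


def test_confusion_matches_double_loop(rng):
    pred = rng.random((20, 20)) > 0.6
    truth = rng.random((20, 20)) > 0.5
    valid = rng.random((20, 20)) > 0.2
    c = ev.confusion(pred, truth, valid)
    tp = tn = fp = fn = 0
    for i in range(20):
        for j in range(20):
            if not valid[i, j]:
                continue
            if pred[i, j] and truth[i, j]:
                tp += 1
            elif pred[i, j]:
                fp += 1
            elif truth[i, j]:
                fn += 1
            else:
                tn += 1
    assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
    assert c.total == int(valid.sum())


def test_metrics_worked_example():
    m = ev.metrics(ev.ConfusionCounts(tp=2, fp=1, fn=1, tn=6))
    assert m["dice"] == pytest.approx(2 / 3)
    assert m["sensitivity"] == pytest.approx(2 / 3)
    assert m["specificity"] == pytest.approx(6 / 7)
    assert m["accuracy"] == pytest.approx(0.8)


def test_metrics_edge_cases():
    perfect = ev.metrics(ev.ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
    assert all(v == 1.0 for v in perfect.values())
    missed = ev.metrics(ev.ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
    assert missed["sensitivity"] == 0.0
    assert missed["dice"] == 0.0
    no_pos = ev.metrics(ev.ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
    assert math.isnan(no_pos["sensitivity"])


@settings(deadline=None, max_examples=1000)
@given(st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)))
def test_metrics_agree_with_brute_force(counts):
    tp, tn, fp, fn = counts
    if tp + tn + fp + fn == 0:
        return
    got = ev.metrics(ev.ConfusionCounts(tp, tn, fp, fn))
    want = brute_metrics(tp, tn, fp, fn)
    for key in want:
        if math.isnan(want[key]):
            assert math.isnan(got[key])
        else:
            assert got[key] == pytest.approx(want[key])


def test_dice_symmetric_in_fp_fn():
    a = ev.metrics(ev.ConfusionCounts(tp=4, tn=10, fp=3, fn=7))["dice"]
    b = ev.metrics(ev.ConfusionCounts(tp=4, tn=10, fp=7, fn=3))["dice"]
    assert a == pytest.approx(b)


def test_frame_agreement_published_worked_example():
    """698 automated vs 730 manual positive frames of 2812 → 4.4% difference."""
    manual = set(range(730))
    auto = set(range(698))
    rep = ev.frame_presence_agreement(auto, manual, 2812)
    assert round(rep["percent_difference"], 1) == 4.4


def test_frame_agreement_set_arithmetic():
    manual = set(range(100))
    auto = manual | {100}
    rep = ev.frame_presence_agreement(auto, manual, 200)
    assert rep["percent_difference"] == pytest.approx(1.0)
    assert rep["fp_frame_fraction_of_manual"] == pytest.approx(0.01)
    assert rep["fn_frame_fraction_of_manual"] == 0.0
    same = ev.frame_presence_agreement(manual, manual, 200)
    assert same["percent_difference"] == 0.0
    empty = ev.frame_presence_agreement(set(), set(), 10)
    assert math.isnan(empty["percent_difference"])


def test_make_folds_122_segments_sizes():
    ids = [f"seg-{i}" for i in range(122)]
    split = ev.make_folds(ids, seed=0)
    sizes = sorted(len(f["test"]) for f in split.folds)
    assert sizes == [24, 24, 24, 25, 25]
    assert all(23 <= s <= 25 for s in sizes)


def test_make_folds_partition_and_roles():
    ids = [f"s{i}" for i in range(22)]
    split = ev.make_folds(ids, seed=3)
    seen = []
    for f in split.folds:
        seen += f["test"]
        assert not (set(f["train"]) & set(f["val"]))
        assert not (set(f["train"]) & set(f["test"]))
        assert not (set(f["val"]) & set(f["test"]))
        assert set(f["train"]) | set(f["val"]) | set(f["test"]) == set(ids)
    assert sorted(seen) == sorted(ids)


def test_make_folds_deterministic_and_minimum():
    ids = [f"s{i}" for i in range(9)]
    a = ev.make_folds(ids, seed=11)
    b = ev.make_folds(ids, seed=11)
    assert a.folds == b.folds
    with pytest.raises(ValueError):
        ev.make_folds(ids[:4], seed=0)


def test_observer_agreement_identical_lists():
    a = [0.1, 0.2, 0.3, 0.4]
    rep = ev.observer_agreement(a, a)
    assert rep.r_squared == pytest.approx(1.0)
    assert rep.bias == 0.0
    assert rep.area_dice == pytest.approx(1.0)


def test_observer_agreement_constant_offset():
    a = np.array([0.1, 0.2, 0.3, 0.4])
    rep = ev.observer_agreement(a, a + 0.1)
    assert rep.bias == pytest.approx(-0.1)
    assert rep.loa_low == pytest.approx(-0.1)
    assert rep.loa_high == pytest.approx(-0.1)


def test_observer_agreement_r2_matches_formula(rng):
    a = rng.random(30)
    b = 0.8 * a + 0.05 * rng.normal(size=30)
    rep = ev.observer_agreement(a, b)
    pred = rep.slope * a + rep.intercept
    ss_res = ((b - pred) ** 2).sum()
    ss_tot = ((b - b.mean()) ** 2).sum()
    assert rep.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-9)


def test_paired_ttest_cases():
    x = [1.0, 2.0, 3.0, 4.0]
    same = ev.paired_ttest(x, x)
    assert same["t"] == 0.0 and same["p"] == 1.0
    # textbook: differences {1,2,3} → t = mean/(sd/sqrt(n)) = 2*sqrt(3)
    res = ev.paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert res["t"] == pytest.approx(2 * math.sqrt(3), rel=1e-9)
    # shift invariance
    shifted = ev.paired_ttest([3.0, 5.0, 7.0], [2.0, 3.0, 4.0])
    assert shifted["t"] == pytest.approx(res["t"], rel=1e-9)


def test_aggregate_folds_mean_and_sd():
    folds = [
        {"sensitivity": 0.8, "specificity": 0.9, "accuracy": 0.85, "dice": 0.7},
        {"sensitivity": 0.6, "specificity": 1.0, "accuracy": 0.95, "dice": 0.5},
    ]
    agg = ev.aggregate_folds(folds)
    assert agg["sensitivity"][0] == pytest.approx(0.7)
    assert agg["sensitivity"][1] == pytest.approx(np.std([0.8, 0.6], ddof=1))
    nan_fold = folds + [{"sensitivity": math.nan, "specificity": 0.95, "accuracy": 0.9, "dice": 0.6}]
    agg2 = ev.aggregate_folds(nan_fold)
    assert agg2["sensitivity"][0] == pytest.approx(0.7)  # NaN excluded
    assert agg2["dice"][0] == pytest.approx(0.6)
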