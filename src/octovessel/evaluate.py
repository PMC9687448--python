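"""Pixel/candidate/frame-level metrics, segment-grouped cross-validation,
and observer-agreement statistics.

Metrics are the standard confusion-matrix quantities: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total and Dice
2TP/(2TP+FP+FN).  Cross-validation folds group strictly by segment so that
near-identical frames never leak across roles.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def confusion(pred: np.ndarray, truth: np.ndarray, valid: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts over the valid region."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if valid is None:
        valid = np.ones_like(pred, dtype=bool)
    else:
        valid = np.asarray(valid).astype(bool)
        if valid.shape != pred.shape:
            raise ValueError("valid mask shape differs")
    p, t = pred[valid], truth[valid]
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy and Dice; undefined denominators → NaN."""
    if c.total == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "accuracy": (c.tp + c.tn) / c.total,
        "dice": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


def aggregate_folds(per_fold: Sequence[dict]) -> dict:
    """Mean ± sd of each metric over folds, skipping NaN (undefined) entries."""
    out = {}
    for key in ("sensitivity", "specificity", "accuracy", "dice"):
        vals = np.array([f[key] for f in per_fold], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[key] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    return out


def frame_presence_agreement(auto_frames: set[int], manual_frames: set[int], total_frames: int) -> dict:
    """Frame-level agreement between automated and manual microvessel presence.

    Percent difference is |#manual − #auto| / #manual × 100; false-positive
    and false-negative frames are reported as fractions of the manual count
    and of all frames.
    """
    if not (all(0 <= f < total_frames for f in auto_frames | manual_frames)):
        raise ValueError("frame indices out of range")
    n_manual, n_auto = len(manual_frames), len(auto_frames)
    fp_frames = auto_frames - manual_frames
    fn_frames = manual_frames - auto_frames
    if n_manual == 0:
        pct = math.nan
    else:
        pct = abs(n_manual - n_auto) / n_manual * 100.0
    return {
        "n_manual": n_manual,
        "n_auto": n_auto,
        "percent_difference": pct,
        "fp_frame_fraction_of_manual": len(fp_frames) / n_manual if n_manual else math.nan,
        "fn_frame_fraction_of_manual": len(fn_frames) / n_manual if n_manual else math.nan,
        "fp_frame_fraction_of_all": len(fp_frames) / total_frames,
        "fn_frame_fraction_of_all": len(fn_frames) / total_frames,
    }


@dataclasses.dataclass
class FoldSplit:
    """Segment-grouped cross-validation folds."""

    folds: list[dict]  # each: {"train": [...], "val": [...], "test": [...]}

    def check(self) -> None:
        all_test = [s for f in self.folds for s in f["test"]]
        if len(all_test) != len(set(all_test)):
            raise AssertionError("a segment appears in two test folds")
        for f in self.folds:
            roles = f["train"] + f["val"] + f["test"]
            if len(roles) != len(set(roles)):
                raise AssertionError("a segment appears in two roles within a fold")


def make_folds(segment_ids: Sequence[str], seed: int = 0, n_folds: int = 5,
               val_fraction: float = 0.18) -> FoldSplit:
    """Shuffle segments into ``n_folds`` near-equal subsets; each subset is the
    test set of one fold and the remainder splits ~82/18 into train/val
    (approximating a 70/15/15 overall assignment)."""
    ids = list(segment_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} segments")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    base, extra = divmod(len(ids), n_folds)
    subsets, at = [], 0
    for k in range(n_folds):
        size = base + (1 if k < extra else 0)
        subsets.append(shuffled[at : at + size])
        at += size
    folds = []
    for k in range(n_folds):
        test = subsets[k]
        rest = [s for j, sub in enumerate(subsets) if j != k for s in sub]
        n_val = max(1, round(val_fraction * len(rest)))
        folds.append({"train": rest[n_val:], "val": rest[:n_val], "test": list(test)})
    split = FoldSplit(folds)
    split.check()
    return split


@dataclasses.dataclass
class AgreementReport:
    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float
    area_dice: float


def observer_agreement(areas_first: Sequence[float], areas_second: Sequence[float]) -> AgreementReport:
    """Repeated-measurement agreement: regression, Bland–Altman, area Dice.

    Differences are first − second; limits of agreement are bias ± 1.96·sd.
    Area Dice is 2·Σmin(a,b) / Σ(a+b) over pairs.
    """
    a = np.asarray(areas_first, dtype=float)
    b = np.asarray(areas_second, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired area lists must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.linregress(a, b)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    dice = float(2.0 * np.minimum(a, b).sum() / (a + b).sum())
    return AgreementReport(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        area_dice=dice,
    )


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> dict:
    """Paired t-test on differences; zero-variance differences are flagged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return {"t": 0.0, "p": 1.0, "degenerate": True}
        return {"t": math.inf if d.mean() > 0 else -math.inf, "p": 0.0, "degenerate": True}
    t, p = stats.ttest_rel(x, y)
    return {"t": float(t), "p": float(p), "degenerate": False}
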