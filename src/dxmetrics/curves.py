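"""Empirical ROC and precision-recall curves with trapezoidal areas.

The sweep is over every distinct observed score: at threshold t a subject is
called positive when score >= t (higher score = more disease-like; use the
``direction`` flag to flip). Tied scores collapse to a single threshold.
The ROC curve carries the (0,0) and (1,1) anchors; AUROC by trapezoid then
equals the Mann-Whitney statistic (probability a random positive outranks a
random negative, ties credited 1/2) exactly. The PR curve anchors recall 0
at the precision of the highest-threshold nonempty prediction set, and AUPRC
integrates the PR polyline by trapezoid on the recall axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, UndefinedCurveError


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    tpr: float
    fpr: float
    precision: float | None


@dataclass(frozen=True)
class Curve:
    """Ordered threshold sweep (descending threshold) plus its AUC."""

    test_name: str
    kind: Literal["roc", "pr"]
    points: tuple[CurvePoint, ...]
    auc: float


def _validate_scores(
    truth: Sequence[int], scores: Sequence[float], direction: str, need_negative: bool
) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(truth, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ConfigError("truth and scores must be 1-D sequences of equal length")
    keep = ~(np.isnan(y) | np.isnan(s))
    y, s = y[keep], s[keep]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ConfigError("truth labels must be 0/1")
    if direction == "le":
        s = -s
    elif direction != "ge":
        raise ConfigError(f"direction must be 'ge' or 'le', got {direction!r}")
    if y.sum() == 0:
        raise UndefinedCurveError("curve undefined: no positive truth labels")
    if need_negative and y.sum() == y.size:
        raise UndefinedCurveError("curve undefined: no negative truth labels")
    return y.astype(bool), s


def _sweep(y: np.ndarray, s: np.ndarray):
    """Cumulative TP/FP counts at each distinct threshold, descending."""
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # last index of each tied block = counts with predicate score >= threshold
    last = np.nonzero(np.diff(s_sorted, append=np.nan))[0]
    return s_sorted[last], tp[last], fp[last]


def roc_curve(
    truth: Sequence[int], scores: Sequence[float], test_name: str = "test",
    direction: str = "ge",
) -> Curve:
    """Empirical ROC curve: one point per distinct score, plus the anchors."""
    y, s = _validate_scores(truth, scores, direction, need_negative=True)
    pos, neg = y.sum(), (~y).sum()
    thresholds, tp, fp = _sweep(y, s)
    pts = [CurvePoint(float("inf"), 0.0, 0.0, None)]
    for t, tpc, fpc in zip(thresholds, tp, fp):
        pts.append(CurvePoint(float(t), tpc / pos, fpc / neg, tpc / (tpc + fpc)))
    if pts[-1].tpr != 1.0 or pts[-1].fpr != 1.0:  # unreachable: full set is last
        pts.append(CurvePoint(float("-inf"), 1.0, 1.0, pos / (pos + neg)))
    return Curve(test_name, "roc", tuple(pts), _trapezoid(pts, "fpr", "tpr"))


def _trapezoid(pts: Iterable[CurvePoint], xattr: str, yattr: str) -> float:
    xs = np.array([getattr(p, xattr) for p in pts], dtype=float)
    ys = np.array([getattr(p, yattr) for p in pts], dtype=float)
    return float(np.trapezoid(ys, xs))


def auroc(truth: Sequence[int], scores: Sequence[float], direction: str = "ge") -> float:
    """Area under the empirical ROC curve.

    Equals the Mann-Whitney statistic: the proportion of (positive, negative)
    pairs in which the positive subject scores higher, counting ties 1/2.
    """
    return roc_curve(truth, scores, direction=direction).auc


def pr_curve(
    truth: Sequence[int], scores: Sequence[float], test_name: str = "test",
    direction: str = "ge",
) -> Curve:
    """Empirical precision-recall curve over all distinct thresholds.

    Recall sweeps 0 -> 1 as the threshold descends; the zero-recall endpoint
    inherits the precision of the highest-threshold (smallest nonempty)
    prediction set.
    """
    y, s = _validate_scores(truth, scores, direction, need_negative=False)
    pos = y.sum()
    thresholds, tp, fp = _sweep(y, s)
    first_precision = tp[0] / (tp[0] + fp[0])
    pts = [CurvePoint(float("inf"), 0.0, 0.0, float(first_precision))]
    for t, tpc, fpc in zip(thresholds, tp, fp):
        pts.append(CurvePoint(float(t), tpc / pos, fpc / max((~y).sum(), 1), tpc / (tpc + fpc)))
    return Curve(test_name, "pr", tuple(pts), _trapezoid(pts, "tpr", "precision"))


def auprc(truth: Sequence[int], scores: Sequence[float], direction: str = "ge") -> float:
    """Area under the PR polyline, trapezoidal on the recall axis."""
    return pr_curve(truth, scores, direction=direction).auc


def overlay_tables(curves: Sequence[Curve]) -> pd.DataFrame:
    """Long-format table of one or more same-kind curves, ready for plotting.

    Columns: test_name, threshold, x, y, auc — with (x, y) = (FPR, TPR) for
    ROC curves and (recall, precision) for PR curves.
    """
    if not curves:
        raise ConfigError("need at least one curve")
    kinds = {c.kind for c in curves}
    if len(kinds) > 1:
        raise ConfigError(f"cannot overlay mixed curve kinds: {sorted(kinds)}")
    kind = curves[0].kind
    rows = []
    for curve in curves:
        for p in curve.points:
            x, y = (p.fpr, p.tpr) if kind == "roc" else (p.tpr, p.precision)
            rows.append(
                {
                    "test_name": curve.test_name,
                    "threshold": p.threshold,
                    "x": x,
                    "y": y,
                    "auc": curve.auc,
                }
            )
    return pd.DataFrame(rows)


def plot_overlay(curves: Sequence[Curve], path: str) -> None:
    """Render overlaid curves of one kind to an image file (AUCs in legend)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = overlay_tables(curves)
    kind = curves[0].kind
    fig, ax = plt.subplots(figsize=(6, 5))
    for curve in curves:
        sub = table[table.test_name == curve.test_name]
        ax.plot(sub.x, sub.y, label=f"{curve.test_name} (AUC = {curve.auc:.3f})")
    if kind == "roc":
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
    else:
        ax.set_xlabel("Recall (sensitivity)")
        ax.set_ylabel("Precision (PPV)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.05)
    ax.legend(loc="lower right" if kind == "roc" else "lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
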