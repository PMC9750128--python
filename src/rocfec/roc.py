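"""Construction, interpolation, averaging and integration of ROC curves.

An ROC curve is represented as an ordered polyline in (FPR, TPR) space
together with the positive/negative counts that generated it.  The curve of
a ranked gene list can be read as a walk: starting at (0, 0), it steps up by
1/n_pos whenever an annotated (positive) gene is encountered and right by
1/n_neg whenever an unannotated (negative) gene is encountered.  The area
under the walk equals the Mann-Whitney U statistic divided by
n_pos * n_neg, i.e. the probability that a random positive outranks a
random negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ScoredLabels",
    "RocCurve",
    "build_roc",
    "auroc",
    "interpolate_curve",
    "average_curves",
]


@dataclass
class ScoredLabels:
    """Per-gene prediction scores paired with binary annotation labels.

    Higher scores mean "more confidently predicted functional".  Labels
    follow the closed-world assumption: 1 for annotated genes, 0 for every
    other gene, even though annotations are typically incomplete.
    """

    ids: list[str]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("gene ids must be unique")
        if len(self.ids) != self.scores.size or self.scores.size != self.labels.size:
            raise ValueError("ids, scores and labels must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(self.labels.size - self.labels.sum())


@dataclass
class RocCurve:
    """Monotone piecewise-linear curve in (FPR, TPR) space.

    ``points`` is an (m, 2) array of (fpr, tpr) vertices, non-decreasing in
    both coordinates, with fpr running from 0 to 1.  Freshly built curves
    start at (0, 0); curves interpolated onto an even FPR grid represent an
    initial vertical segment by its upper TPR, so their first vertex can sit
    at (0, t) with t > 0.
    """

    points: np.ndarray
    n_pos: int
    n_neg: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("points must be an (m >= 2, 2) array")
        if np.any(pts < -1e-12) or np.any(pts > 1 + 1e-12):
            raise ValueError("coordinates must lie in [0, 1]")
        if np.any(np.diff(pts[:, 0]) < -1e-12) or np.any(np.diff(pts[:, 1]) < -1e-12):
            raise ValueError("fpr and tpr must be non-decreasing")
        if abs(pts[0, 0]) > 1e-12 or abs(pts[-1, 0] - 1) > 1e-12 or abs(pts[-1, 1] - 1) > 1e-12:
            raise ValueError("curve must start at fpr=0 and end at (1, 1)")
        self.points = np.clip(pts, 0.0, 1.0)

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]

    def __len__(self) -> int:
        return self.points.shape[0]


def build_roc(
    data: ScoredLabels,
    tie_policy: Literal["walk", "trapezoid"] = "trapezoid",
) -> RocCurve:
    """Build the ROC curve of a scored, labelled gene list.

    With distinct scores the curve is the classic walk: n_pos vertical steps
    of height 1/n_pos and n_neg horizontal steps of width 1/n_neg, one per
    gene in decreasing score order.  Tied scores are handled per
    ``tie_policy``: ``"trapezoid"`` (default) draws a single diagonal across
    each tie block, so the area matches the Mann-Whitney convention of
    counting tied positive/negative pairs as 1/2; ``"walk"`` orders
    positives first within a tie block, reproducing the step-curve
    construction exactly.
    """
    n_pos, n_neg = data.n_pos, data.n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC curve undefined: need at least one positive and one negative label"
        )
    order = np.argsort(-data.scores, kind="stable")
    scores = data.scores[order]
    labels = data.labels[order]

    # tie-block boundaries in the descending score list
    boundaries = np.flatnonzero(np.diff(scores)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [labels.size]))

    cum_pos = np.concatenate(([0], np.cumsum(labels)))
    cum_neg = np.concatenate(([0], np.cumsum(1 - labels)))

    if tie_policy == "trapezoid":
        fpr = np.concatenate(([0.0], cum_neg[stops] / n_neg))
        tpr = np.concatenate(([0.0], cum_pos[stops] / n_pos))
        pts = np.column_stack((fpr, tpr))
    elif tie_policy == "walk":
        verts = [(0.0, 0.0)]
        for s, e in zip(starts, stops):
            x0, y0 = cum_neg[s] / n_neg, cum_pos[s] / n_pos
            x1, y1 = cum_neg[e] / n_neg, cum_pos[e] / n_pos
            if y1 > y0:
                verts.append((x0, y1))
            if x1 > x0:
                verts.append((x1, y1))
        pts = np.asarray(verts)
    else:
        raise ValueError(f"unknown tie_policy: {tie_policy!r}")

    # drop consecutive duplicate vertices
    keep = np.concatenate(([True], np.any(np.diff(pts, axis=0) != 0, axis=1)))
    return RocCurve(pts[keep], n_pos=n_pos, n_neg=n_neg, meta={"tie_policy": tie_policy})


def auroc(curve: RocCurve) -> float:
    """Area under the curve by the trapezoidal rule."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _tpr_at(points: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """TPR of the polyline at each grid fpr, upper value on vertical jumps."""
    x, y = points[:, 0], points[:, 1]
    # rightmost vertex with fpr <= g: on a vertical segment this picks the
    # supremum tpr, which preserves area under resampling better than the
    # lower envelope
    idx = np.searchsorted(x, grid, side="right") - 1
    idx = np.clip(idx, 0, x.size - 1)
    out = np.empty_like(grid)
    exact = x[idx] == grid
    out[exact] = y[idx[exact]]
    j = idx[~exact]
    frac = (grid[~exact] - x[j]) / (x[j + 1] - x[j])
    out[~exact] = y[j] + frac * (y[j + 1] - y[j])
    return out


def interpolate_curve(curve: RocCurve, n_points: int) -> RocCurve:
    """Resample the curve at ``n_points`` evenly spaced FPR values.

    The grid includes 0 and 1; the TPR at each grid FPR is the linear
    interpolation of the input polyline, with vertical segments represented
    by their upper TPR.  Idempotent for a fixed grid size.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(0.0, 1.0, n_points)
    tpr = _tpr_at(curve.points, grid)
    meta = dict(curve.meta, interpolated=n_points)
    return RocCurve(np.column_stack((grid, tpr)), curve.n_pos, curve.n_neg, meta)


def average_curves(curves: Sequence[RocCurve], n_points: int = 200) -> RocCurve:
    """Vertically average curves on a common evenly spaced FPR grid.

    Used to combine cross-validation fold curves into a single reported
    curve.  The positive/negative counts of the average are the rounded
    means of the inputs, which downstream normalized-KS statistics use as
    the effective sample size.
    """
    if len(curves) == 0:
        raise ValueError("cannot average an empty list of curves")
    grid = np.linspace(0.0, 1.0, n_points)
    tprs = np.stack([_tpr_at(c.points, grid) for c in curves])
    mean_tpr = tprs.mean(axis=0)
    n_pos = int(round(np.mean([c.n_pos for c in curves])))
    n_neg = int(round(np.mean([c.n_neg for c in curves])))
    meta = {"averaged": len(curves), "interpolated": n_points}
    return RocCurve(np.column_stack((grid, mean_tpr)), n_pos, n_neg, meta)
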