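"""Piecewise-linear summarization of ROC curves.

Two shape operations: replacing a curve by chords through the endpoints of
its longest straight segment (a 2-4 point approximation whose area error
measures how well two or three discrete gene classes explain performance),
and finding the subcurve whose flip — point reflection about the midpoint
of its chord, i.e. inverting the classifier within that score range —
maximizes the area under the curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fec import Subcurve, extract_fecs
from .roc import RocCurve, auroc, interpolate_curve

__all__ = ["SegmentApproximation", "longest_segment_approximation", "optimal_flip", "flip_subcurve"]


@dataclass
class SegmentApproximation:
    """A 2-4 anchor-point chord approximation of an ROC curve."""

    anchor_points: np.ndarray  # (k, 2), k in 2..4, includes (0,0) and (1,1)
    auroc_original: float
    auroc_approx: float

    @property
    def rel_error(self) -> float:
        return abs(self.auroc_approx - self.auroc_original) / self.auroc_original


def longest_segment_approximation(
    curve: RocCurve,
    n_total_pos: Optional[int] = None,
    d_norm_max: float = 1.0,
    min_fpr_span: float = 0.05,
    grid: Optional[int] = 200,
) -> SegmentApproximation:
    """Approximate a curve by chords through its longest straight segment.

    The longest detected FEC supplies two anchor points; the curve is
    replaced by straight chords (0,0) -> (FPR0,TPR0) -> (FPR1,TPR1) -> (1,1).
    When the segment already touches (0,0) or (1,1) the anchor list
    collapses to three (or two) points.  Areas are trapezoidal; the
    relative error is taken against the original area.
    """
    fecs = extract_fecs(curve, n_total_pos, d_norm_max, min_fpr_span, grid)
    if not fecs:
        raise ValueError("no straight segment found: curve is not approximable")
    longest = max(fecs, key=lambda f: f.fpr_span)
    p0 = np.asarray(longest.subcurve.start)
    p1 = np.asarray(longest.subcurve.end)
    anchors = [np.zeros(2), p0, p1, np.ones(2)]
    dedup = [anchors[0]]
    for a in anchors[1:]:
        if not np.allclose(a, dedup[-1], atol=1e-12):
            dedup.append(a)
    pts = np.vstack(dedup)
    approx = RocCurve(pts, curve.n_pos, curve.n_neg, meta={"approximation": True})
    return SegmentApproximation(pts, auroc_original=auroc(curve), auroc_approx=auroc(approx))


def flip_subcurve(curve: RocCurve, i: int, j: int) -> RocCurve:
    """Flip the subcurve between vertices i and j (inclusive).

    The interior vertices are point-reflected about the midpoint of the
    chord joining vertices i and j and their order reversed, which keeps
    FPR non-decreasing and fixes the endpoints.  Flipping twice restores
    the curve.
    """
    if not (0 <= i < j < len(curve)):
        raise ValueError("need 0 <= i < j < number of vertices")
    pts = curve.points.copy()
    x0, y0 = pts[i]
    x1, y1 = pts[j]
    inner = pts[i + 1 : j]
    pts[i + 1 : j] = np.column_stack(
        ((x0 + x1) - inner[::-1, 0], (y0 + y1) - inner[::-1, 1])
    )
    return RocCurve(pts, curve.n_pos, curve.n_neg, meta=dict(curve.meta, flipped=(i, j)))


def optimal_flip(
    curve: RocCurve, grid: Optional[int] = None
) -> tuple[Optional[Subcurve], float]:
    """Find the subcurve flip that maximizes the trapezoidal AUROC.

    Flipping the subcurve between vertices i and j changes the area by
    (x_j - x_i)(y_i + y_j) - 2 * A_sub, where A_sub is the trapezoidal area
    under the subcurve — the reflected polyline's area is the chord
    rectangle minus the original.  The identity (no flip) is always a
    candidate, so the returned AUROC is >= the original.  Returns
    (best subcurve or None for the identity, best AUROC).
    """
    work = interpolate_curve(curve, grid) if grid is not None else curve
    x, y = work.fpr, work.tpr
    base = auroc(work)
    # prefix trapezoid areas
    seg = 0.5 * (y[1:] + y[:-1]) * np.diff(x)
    T = np.concatenate(([0.0], np.cumsum(seg)))
    ii, jj = np.triu_indices(x.size, k=1)
    gain = (x[jj] - x[ii]) * (y[ii] + y[jj]) - 2.0 * (T[jj] - T[ii])
    k = int(np.argmax(gain))
    if gain[k] <= 1e-15:
        return None, base
    i, j = int(ii[k]), int(jj[k])
    return Subcurve(work.points[i : j + 1]), base + float(gain[k])
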