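"""Detection of straight ROC subcurves (functional equivalence classes).

A straight segment of an ROC curve indicates that, within the score range
it covers, annotated and unannotated genes are interchangeable: their score
distributions are locally identical, so the walk behaves like a random mix
of up and right steps.  Such a segment groups genes into a functional
equivalence class (FEC).

Linearity of a subcurve is tested by rescaling it to the unit square and
measuring its maximal deviation from the diagonal, D_n = sup |TPR' - FPR'|.
Normalizing by the square root of the number of positives the subcurve
spans, D' = D_n * sqrt(n), puts the statistic on the scale of the classical
one-sample Kolmogorov-Smirnov test: under local label interchangeability
the rescaled subcurve is a random walk bridge and D' follows the asymptotic
Kolmogorov distribution.  Subcurves with D' <= 1 (asymptotic p >= 0.27) are
tagged linear, and the final FEC list is assembled by iteratively taking
the longest non-overlapping linear subcurves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .roc import RocCurve, interpolate_curve

__all__ = [
    "Subcurve",
    "FEC",
    "rescale_subcurve",
    "ks_statistic",
    "normalized_ks",
    "ks_pvalue",
    "enumerate_candidates",
    "extract_fecs",
    "fec_coverage",
]


@dataclass
class Subcurve:
    """A contiguous run of curve vertices from ``start`` to ``end``."""

    points: np.ndarray  # (k, 2) vertices, endpoints inclusive

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("subcurve needs at least two (fpr, tpr) vertices")
        self.points = pts

    @property
    def start(self) -> tuple[float, float]:
        return tuple(self.points[0])

    @property
    def end(self) -> tuple[float, float]:
        return tuple(self.points[-1])

    @property
    def fpr_span(self) -> float:
        return float(self.points[-1, 0] - self.points[0, 0])

    @property
    def tpr_span(self) -> float:
        return float(self.points[-1, 1] - self.points[0, 1])


@dataclass
class FEC:
    """A detected straight subcurve with its linearity statistics.

    ``ks_raw``, ``ks_norm`` and ``p_value`` are ``None`` when the subcurve
    is degenerate (zero FPR or TPR span): a run of identical steps is a
    perfect straight line for which the KS statistic is undefined (NA).
    """

    subcurve: Subcurve
    ks_raw: Optional[float]
    n_sub: int
    ks_norm: Optional[float]
    p_value: Optional[float]

    @property
    def fpr_span(self) -> float:
        return self.subcurve.fpr_span

    @property
    def tpr_span(self) -> float:
        return self.subcurve.tpr_span

    @property
    def slope(self) -> float:
        return self.tpr_span / self.fpr_span if self.fpr_span > 0 else math.inf


def rescale_subcurve(sub: Subcurve) -> Subcurve:
    """Affinely map a subcurve onto the unit square.

    FPR' = (FPR - FPR0) / (FPR1 - FPR0), TPR' = (TPR - TPR0) / (TPR1 - TPR0).
    Raises ``ValueError`` on zero FPR or TPR span (degenerate subcurve, for
    which the KS statistic is reported as missing).
    """
    dx, dy = sub.fpr_span, sub.tpr_span
    if dx <= 0 or dy <= 0:
        raise ValueError("degenerate subcurve: zero fpr or tpr span")
    x0, y0 = sub.start
    pts = (sub.points - (x0, y0)) / (dx, dy)
    return Subcurve(pts)


def ks_statistic(sub: Subcurve) -> float:
    """Sup deviation |TPR' - FPR'| of the rescaled subcurve from its diagonal.

    The deviation is piecewise linear along the polyline, so the supremum is
    attained at a vertex.
    """
    r = rescale_subcurve(sub)
    return float(np.max(np.abs(r.points[:, 1] - r.points[:, 0])))


def normalized_ks(sub: Subcurve, n_total_pos: int) -> FEC:
    """Normalized KS statistic D' = D_n * sqrt(n) of a subcurve.

    ``n`` is the number of positives the subcurve spans, estimated from the
    curve-wide positive count as round(n_total_pos * tpr_span) and floored
    at 1.  Degenerate subcurves get missing statistics.
    """
    if n_total_pos < 1:
        raise ValueError("n_total_pos must be >= 1")
    n_sub = max(1, round(n_total_pos * sub.tpr_span))
    try:
        d = ks_statistic(sub)
    except ValueError:
        return FEC(sub, ks_raw=None, n_sub=n_sub, ks_norm=None, p_value=None)
    d_norm = d * math.sqrt(n_sub)
    return FEC(sub, ks_raw=d, n_sub=n_sub, ks_norm=d_norm, p_value=ks_pvalue(d_norm))


def ks_pvalue(d_norm: float, tol: float = 1e-10) -> float:
    """Asymptotic Kolmogorov survival function Q(lambda).

    Q(lambda) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2), the
    limiting null distribution of sqrt(n) * D_n for the one-sample
    two-sided KS test (the asymptotic branch of R's ks.test).  The series
    is truncated once terms fall below ``tol``; the result is clamped to
    [0, 1].
    """
    if d_norm < 0:
        raise ValueError("normalized KS statistic must be >= 0")
    if d_norm == 0:
        return 1.0
    total = 0.0
    sign = 1.0
    for k in range(1, 100_000):
        term = math.exp(-2.0 * k * k * d_norm * d_norm)
        total += sign * term
        if term < tol:
            break
        sign = -sign
    return min(1.0, max(0.0, 2.0 * total))


def enumerate_candidates(
    curve: RocCurve, min_fpr_span: float = 0.05
) -> list[Subcurve]:
    """All vertex-pair subcurves spanning at least ``min_fpr_span`` in FPR.

    The curve is taken as-is; interpolate beforehand (or via
    ``extract_fecs``'s grid) to bound the quadratic enumeration.
    """
    pts = curve.points
    x = pts[:, 0]
    out = []
    for i in range(len(x) - 1):
        for j in range(i + 1, len(x)):
            if x[j] - x[i] >= min_fpr_span:
                out.append(Subcurve(pts[i : j + 1]))
    return out


def _pairwise_ks(pts: np.ndarray) -> np.ndarray:
    """D_n for every vertex pair (i, j), NaN where the span is degenerate.

    Uses the cross-product form: the deviation of vertex k from the
    (i, j) diagonal is |(y_k - y_i)(x_j - x_i) - (x_k - x_i)(y_j - y_i)|
    divided by the FPR and TPR spans, maximized over i <= k <= j.
    """
    x, y = pts[:, 0], pts[:, 1]
    m = x.size
    D = np.full((m, m), np.nan)
    for i in range(m - 1):
        dx = x[i:] - x[i]
        dy = y[i:] - y[i]
        cross = np.abs(dy[:, None] * dx[None, :] - dx[:, None] * dy[None, :])
        running = np.maximum.accumulate(cross, axis=0)
        sup = np.diagonal(running)  # max_{i<=k<=j} |cross(k; i, j)|
        span = dx * dy
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(span > 0, sup / span, np.nan)
        D[i, i:] = d
    return D


def extract_fecs(
    curve: RocCurve,
    n_total_pos: Optional[int] = None,
    d_norm_max: float = 1.0,
    min_fpr_span: float = 0.05,
    grid: Optional[int] = 200,
) -> list[FEC]:
    """Iteratively extract the longest non-overlapping straight subcurves.

    Candidate subcurves are all vertex pairs of the working curve (the
    input interpolated to ``grid`` evenly spaced FPR points, or its native
    vertices when ``grid`` is None) whose FPR span is at least
    ``min_fpr_span``.  A candidate is linear when its normalized KS
    statistic D' is at most ``d_norm_max``, or when its TPR span is zero
    (a horizontal run is a perfect straight line with undefined KS).
    Selection is greedy: repeatedly take the linear candidate with the
    largest FPR span (ties: smaller D', then smaller start FPR), discard
    every candidate sharing interior FPR with it, stop when none remain.

    ``n_total_pos`` defaults to the curve's own positive count; pass an
    explicit value for digitized curves with unknown totals (100 is the
    convention used for literature curves).
    """
    if n_total_pos is None:
        n_total_pos = curve.n_pos
    if n_total_pos < 1:
        raise ValueError("n_total_pos must be >= 1")
    work = interpolate_curve(curve, grid) if grid is not None else curve
    pts = work.points
    x, y = pts[:, 0], pts[:, 1]
    m = x.size

    D = _pairwise_ks(pts)
    ii, jj = np.triu_indices(m, k=1)
    span = x[jj] - x[ii]
    ok_span = span >= min_fpr_span - 1e-12
    d_raw = D[ii, jj]
    tspan = y[jj] - y[ii]
    n_sub = np.maximum(1, np.round(n_total_pos * tspan)).astype(int)
    d_norm = d_raw * np.sqrt(n_sub)
    degenerate = np.isnan(d_raw)
    linear = ok_span & (degenerate | (d_norm <= d_norm_max + 1e-12))

    cand_i = ii[linear]
    cand_j = jj[linear]
    cand_span = span[linear]
    # degenerate (perfectly straight horizontal) candidates rank as D' = 0
    cand_dn = np.where(np.isnan(d_norm[linear]), 0.0, d_norm[linear])

    order = np.lexsort((x[cand_i], cand_dn, -cand_span))
    chosen: list[tuple[int, int]] = []
    alive = np.ones(cand_i.size, dtype=bool)
    for k in order:
        if not alive[k]:
            continue
        i, j = int(cand_i[k]), int(cand_j[k])
        chosen.append((i, j))
        # drop candidates overlapping (i, j) in fpr interior
        overlap = (x[cand_i] < x[j] - 1e-12) & (x[cand_j] > x[i] + 1e-12)
        alive &= ~overlap

    fecs = [normalized_ks(Subcurve(pts[i : j + 1]), n_total_pos) for i, j in sorted(chosen)]
    return fecs


def fec_coverage(fecs: list[FEC]) -> float:
    """Total fraction of the FPR axis covered by a non-overlapping FEC list."""
    ivals = sorted((f.subcurve.start[0], f.subcurve.end[0]) for f in fecs)
    for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
        if b0 < a1 - 1e-12:
            raise ValueError("FECs overlap in fpr")
    return float(sum(b - a for a, b in ivals))
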