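import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import kolmogorov

from rocfec import (
    RocCurve,
    ScoredLabels,
    Subcurve,
    build_roc,
    enumerate_candidates,
    extract_fecs,
    fec_coverage,
    ks_pvalue,
    ks_statistic,
    normalized_ks,
    rescale_subcurve,
)
from conftest import random_scored_labels


class TestRescale:
    def test_midpoint_maps_to_midpoint(self):
        sub = Subcurve(np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6]]))
        r = rescale_subcurve(sub)
        np.testing.assert_allclose(r.points, [[0, 0], [0.5, 0.5], [1, 1]])

    def test_unit_subcurve_unchanged(self):
        pts = np.array([[0, 0], [0.3, 0.7], [1, 1.0]])
        np.testing.assert_allclose(rescale_subcurve(Subcurve(pts)).points, pts)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.random(6))
        y = np.sort(rng.random(6))
        if x[-1] - x[0] < 1e-6 or y[-1] - y[0] < 1e-6:
            return
        once = rescale_subcurve(Subcurve(np.column_stack((x, y))))
        twice = rescale_subcurve(once)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-12)

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rescale_subcurve(Subcurve(np.array([[0.2, 0.1], [0.2, 0.9]])))


class TestKsStatistic:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(0, 0), (0.5, 0.5), (1, 1)], 0.0),  # exact diagonal
            ([(0, 0), (0, 1), (1, 1)], 1.0),  # perfect step
            ([(0, 0), (0.25, 0.75), (1, 1)], 0.5),  # max vertex deviation
        ],
    )
    def test_examples(self, points, expected):
        assert ks_statistic(Subcurve(np.asarray(points, float))) == pytest.approx(expected)


class TestNormalizedKs:
    def test_worked_example(self):
        # D_n = 0.38013 over 5 positives gives D' = 0.85 and p = 0.47
        sub = Subcurve(np.array([[0, 0], [0.25, 0.25 + 0.38013], [1, 1.0]]))
        fec = normalized_ks(sub, n_total_pos=5)
        assert fec.n_sub == 5
        assert fec.ks_norm == pytest.approx(0.85, abs=0.005)
        assert fec.p_value == pytest.approx(0.47, abs=0.005)

    def test_zero_deviation(self):
        fec = normalized_ks(Subcurve(np.array([[0, 0], [1, 1.0]])), 50)
        assert fec.ks_norm == 0.0 and fec.p_value == 1.0

    def test_scaling_with_n(self):
        sub = Subcurve(np.array([[0, 0], [0.45, 0.55], [1, 1.0]]))
        fec = normalized_ks(sub, n_total_pos=100)
        assert fec.ks_norm == pytest.approx(0.1 * 10)

    def test_degenerate_gets_missing_stats(self):
        flat = Subcurve(np.array([[0.1, 0.5], [0.6, 0.5]]))
        fec = normalized_ks(flat, 100)
        assert fec.ks_raw is None and fec.ks_norm is None and fec.p_value is None
        assert fec.fpr_span == pytest.approx(0.5)


class TestKsPvalue:
    @pytest.mark.parametrize(
        "lam, expected", [(1.0, 0.27), (0.85, 0.47)]
    )
    def test_reference_values(self, lam, expected):
        assert round(ks_pvalue(lam), 2) == expected

    def test_reference_value_with_rounded_statistic(self):
        # a statistic reported as 1.2 to 1 d.p. pairs with p ~ 0.12
        assert ks_pvalue(1.2) == pytest.approx(0.12, abs=0.01)

    def test_boundaries(self):
        assert ks_pvalue(0.0) == 1.0
        assert ks_pvalue(50.0) == 0.0
        with pytest.raises(ValueError):
            ks_pvalue(-0.1)

    def test_strictly_decreasing(self):
        # below ~0.35 the survival function is 1 to double precision
        lams = np.linspace(0.4, 3, 60)
        vals = [ks_pvalue(l) for l in lams]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_matches_jacobi_theta_form(self):
        # dual series: K(x) = sqrt(2 pi)/x sum exp(-(2k-1)^2 pi^2 / (8 x^2))
        for lam in np.linspace(0.3, 3, 28):
            cdf = (math.sqrt(2 * math.pi) / lam) * sum(
                math.exp(-((2 * k - 1) ** 2) * math.pi**2 / (8 * lam**2))
                for k in range(1, 50)
            )
            assert ks_pvalue(lam) == pytest.approx(1 - cdf, abs=1e-8)

    def test_matches_scipy_kolmogorov(self):
        for lam in np.linspace(0.1, 4, 40):
            assert ks_pvalue(lam) == pytest.approx(kolmogorov(lam), abs=1e-10)


class TestEnumerate:
    def grid_curve(self, n):
        g = np.linspace(0, 1, n)
        return RocCurve(np.column_stack((g, g)), 10, 10)

    def test_five_point_grid_min_half(self):
        assert len(enumerate_candidates(self.grid_curve(5), 0.5)) == 6

    def test_full_span_only(self):
        cands = enumerate_candidates(self.grid_curve(5), 1.0)
        assert len(cands) == 1 and cands[0].fpr_span == 1.0

    @pytest.mark.parametrize("m", [4, 7, 11])
    def test_zero_min_span_counts_all_pairs(self, m):
        assert len(enumerate_candidates(self.grid_curve(m), 0.0)) == m * (m - 1) // 2


class TestExtractFecs:
    def test_diagonal_yields_single_full_fec(self):
        g = np.linspace(0, 1, 100)
        curve = RocCurve(np.column_stack((g, g)), 50, 50)
        fecs = extract_fecs(curve, 50)
        assert len(fecs) == 1
        assert fecs[0].fpr_span == pytest.approx(1.0)
        assert fecs[0].ks_norm == pytest.approx(0.0, abs=1e-9)

    def test_two_exact_segments(self):
        curve = RocCurve(np.array([[0, 0], [0.2, 0.8], [1, 1.0]]), 100, 100)
        fecs = extract_fecs(curve, 100, grid=None)
        assert len(fecs) == 2
        assert sorted(round(f.fpr_span, 6) for f in fecs) == [0.2, 0.8]
        assert all(f.ks_raw == pytest.approx(0, abs=1e-12) for f in fecs)

    def test_perfect_classifier_horizontal_tail_is_degenerate_fec(self):
        curve = RocCurve(np.array([[0, 0], [0, 1], [1, 1.0]]), 20, 20)
        fecs = extract_fecs(curve, 20, grid=None)
        assert len(fecs) == 1
        assert fecs[0].ks_raw is None  # perfect straight line, KS undefined
        assert fecs[0].fpr_span == pytest.approx(1.0)

    def test_detection_invariant_to_monotone_score_transform(self, rng):
        data = random_scored_labels(rng, n=300, n_pos=60)
        warped = ScoredLabels(data.ids, np.exp(2 * data.scores) + 1, data.labels)
        f1 = extract_fecs(build_roc(data))
        f2 = extract_fecs(build_roc(warped))
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            np.testing.assert_allclose(a.subcurve.points, b.subcurve.points, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_fecs_never_overlap_and_coverage_bounded(self, seed):
        rng = np.random.default_rng(seed)
        data = random_scored_labels(rng, n=150, n_pos=int(rng.integers(5, 80)))
        fecs = extract_fecs(build_roc(data), grid=100)
        spans = sorted((f.subcurve.start[0], f.subcurve.end[0]) for f in fecs)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert b0 >= a1 - 1e-12
        assert fec_coverage(fecs) <= 1 + 1e-12


class TestCoverage:
    def test_sum_of_spans(self):
        curve = RocCurve(np.array([[0, 0], [0.2, 0.8], [1, 1.0]]), 100, 100)
        fecs = extract_fecs(curve, 100, grid=None)
        assert fec_coverage(fecs) == pytest.approx(1.0)
        assert fec_coverage([]) == 0.0

    def test_overlap_rejected(self):
        curve = RocCurve(np.array([[0, 0], [0.2, 0.8], [1, 1.0]]), 100, 100)
        fecs = extract_fecs(curve, 100, grid=None)
        with pytest.raises(ValueError, match="overlap"):
            fec_coverage(fecs + [fecs[-1]])
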