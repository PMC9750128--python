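import numpy as np
import pytest

from rocfec import RocCurve, ScoredLabels


@pytest.fixture
def rng():
    return np.random.default_rng(20220101)


def random_scored_labels(rng, n=200, n_pos=40, ties=False):
    scores = rng.normal(size=n)
    if ties:
        scores = np.round(scores, 1)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, n_pos, replace=False)] = 1
    return ScoredLabels([f"g{i}" for i in range(n)], scores, labels)


def mann_whitney_auroc(data: ScoredLabels) -> float:
    """Brute-force pair counting: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = data.scores[data.labels == 1]
    neg = data.scores[data.labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


def random_monotone_curve(rng, m=30, n_pos=50, n_neg=50) -> RocCurve:
    x = np.sort(np.concatenate(([0.0, 1.0], rng.random(m - 2))))
    y = np.sort(np.concatenate(([0.0, 1.0], rng.random(m - 2))))
    return RocCurve(np.column_stack((x, y)), n_pos, n_neg)
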