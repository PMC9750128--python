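"""Network preparation transforms.

Three standard preprocessing steps for building dense gene networks from
sparse interaction data: shortest-path propagation (weight = inverse hop
distance, densifying a sparse interaction network with indirect
connections), TF-IDF weighted cosine similarity over one-hot feature
matrices (e.g. protein-domain annotations), and top-fraction binarization
of a real-valued interaction score matrix (e.g. drug-target combined
scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from sklearn.metrics.pairwise import cosine_similarity

from .egad import WeightedNetwork

__all__ = [
    "OneHotFeatures",
    "shortest_path_propagation",
    "tfidf_cosine",
    "top_fraction_binarize",
]


@dataclass
class OneHotFeatures:
    """Binary item-by-feature indicator matrix (e.g. protein x domain)."""

    item_ids: list[str]
    feature_ids: list[str]
    indicator: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if ind.shape != (len(self.item_ids), len(self.feature_ids)):
            raise ValueError("indicator must be items x features")
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicator must be binary")
        self.indicator = ind.astype(float)


def shortest_path_propagation(net: WeightedNetwork) -> WeightedNetwork:
    """Propagate interactions: weight = 1 / (hop-count shortest path).

    Edges are the nonzero entries of the input; distances are unweighted
    hop counts.  Self-weights are 1 and disconnected pairs get weight 0.
    Adding an edge can only shorten paths, so propagation is monotone.
    """
    adj = csr_matrix((net.weights > 0).astype(float))
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    with np.errstate(divide="ignore"):
        w = 1.0 / dist
    w[~np.isfinite(w)] = 0.0
    np.fill_diagonal(w, 1.0)
    return WeightedNetwork(net.gene_ids, w)


def tfidf_cosine(
    features: OneHotFeatures, idf: Literal["smooth", "classic"] = "smooth"
) -> WeightedNetwork:
    """Item-item cosine similarity of the TF-IDF weighted indicator.

    Each feature is down-weighted by its document frequency df:
    smooth idf (default) = ln((1 + n) / (1 + df)) + 1, which stays positive
    and finite for ubiquitous features; classic idf = ln(n / df).  Items
    with no features get a zero similarity row (with a warning); diagonal
    entries of supported rows are 1.
    """
    ind = features.indicator
    n_items = ind.shape[0]
    if n_items < 2:
        raise ValueError("need at least two items")
    df = ind.sum(axis=0)
    with np.errstate(divide="ignore"):
        if idf == "smooth":
            idf_w = np.log((1.0 + n_items) / (1.0 + df)) + 1.0
        elif idf == "classic":
            idf_w = np.where(df > 0, np.log(n_items / np.maximum(df, 1)), 0.0)
        else:
            raise ValueError(f"unknown idf variant: {idf!r}")
    weighted = ind * idf_w
    empty = ind.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} items have no features; similarity set to 0")
    sim = cosine_similarity(weighted)
    sim[empty, :] = 0.0
    sim[:, empty] = 0.0
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, np.where(empty, 0.0, 1.0))
    return WeightedNetwork(features.item_ids, sim)


def top_fraction_binarize(
    item_ids: list[str],
    feature_ids: list[str],
    scores: np.ndarray,
    fraction: float = 0.1,
    min_items: int = 20,
) -> OneHotFeatures:
    """Keep the globally top-scoring fraction of nonzero interactions.

    The threshold is the score of the ceil(fraction * n_nonzero)-th largest
    nonzero entry, applied globally (not per feature); entries >= threshold
    become 1.  Features retained by fewer than ``min_items`` items are then
    dropped, as are items left with no features.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    s = np.asarray(scores, dtype=float)
    if s.shape != (len(item_ids), len(feature_ids)):
        raise ValueError("scores must be items x features")
    nonzero = s[s > 0]
    if nonzero.size == 0:
        raise ValueError("score matrix has no positive entries")
    k = max(1, int(np.ceil(fraction * nonzero.size)))
    thresh = np.sort(nonzero)[-k]
    ind = ((s > 0) & (s >= thresh)).astype(float)

    keep_feat = ind.sum(axis=0) >= min_items
    ind = ind[:, keep_feat]
    feats = [f for f, k_ in zip(feature_ids, keep_feat) if k_]
    keep_item = ind.sum(axis=1) > 0
    ind = ind[keep_item]
    items = [i for i, k_ in zip(item_ids, keep_item) if k_]
    if not feats or not items:
        raise ValueError("no features or items survive the min_items filter")
    return OneHotFeatures(items, feats, ind)
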