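"""Simulation models with controlled modularity.

Two generators validate the reading of straight ROC segments as discrete
functional classes:

* **Gaussian model** — each gene has a latent functional state with mean
  score mu; assessing a gene draws N(mu, sigma).  A first noisy assessment
  annotates every gene whose score exceeds a threshold; a second,
  independent assessment at a chosen noise level re-ranks the genes, and
  the agreement between the two is summarized as an ROC curve.  With few
  discrete states and low re-assessment noise the curve is close to
  piecewise linear, one straight segment per state.

* **Network model** — genes sit in pre-defined communities; annotation
  labels are drawn per community with state-dependent probabilities, and a
  block-structured weighted network with tunable within-community mean
  weight controls how modular the annotation looks to neighbor voting.

Presets reproduce the standard configurations: an on/off model (two
states), an on/low/off model (three states) and a continuous model (four
states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .egad import AnnotationMatrix, WeightedNetwork
from .roc import ScoredLabels

__all__ = [
    "GaussianSimConfig",
    "NetworkSimConfig",
    "GAUSSIAN_PRESETS",
    "NETWORK_ANNOTATION_PRESETS",
    "simulate_gaussian",
    "simulate_network",
]


@dataclass
class GaussianSimConfig:
    """Configuration of the Gaussian mixture score model.

    ``state_means`` and ``mixing_proportions`` define the latent states;
    ``annotation_sigma`` is the noise of the annotating assessment, whose
    scores are thresholded at ``annotation_threshold`` to produce labels;
    ``assessment_sigmas`` are the noise levels of the independent
    re-assessments.
    """

    n_genes: int = 10_000
    state_means: Sequence[float] = (0.0, 1.0)
    mixing_proportions: Sequence[float] = (0.8, 0.2)
    annotation_sigma: float = 0.5
    annotation_threshold: float = 0.2
    assessment_sigmas: Sequence[float] = (0.1, 0.2, 0.3, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.mixing_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if len(self.state_means) != props.size:
            raise ValueError("state_means and mixing_proportions must align")
        if self.annotation_sigma <= 0 or any(s <= 0 for s in self.assessment_sigmas):
            raise ValueError("sigmas must be positive")
        if not all(np.isfinite(self.state_means)):
            raise ValueError("state means must be finite")
        if self.n_genes < 2:
            raise ValueError("need at least two genes")


# state means, mixing proportions, annotation sigma — the standard trio of
# two-, three- and four-state configurations
GAUSSIAN_PRESETS: dict[str, dict] = {
    "on_off": dict(state_means=(0.0, 1.0), mixing_proportions=(0.8, 0.2),
                   annotation_sigma=1 / 2),
    "on_low_off": dict(state_means=(0.0, 0.5, 1.0), mixing_proportions=(0.5, 0.3, 0.2),
                       annotation_sigma=1 / 3),
    "continuous": dict(state_means=(0.0, 1 / 3, 2 / 3, 1.0),
                       mixing_proportions=(0.4, 0.3, 0.2, 0.1),
                       annotation_sigma=1 / 4),
}


def gaussian_preset(name: str, **overrides) -> GaussianSimConfig:
    if name not in GAUSSIAN_PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(GAUSSIAN_PRESETS)}")
    return GaussianSimConfig(**{**GAUSSIAN_PRESETS[name], **overrides})


def simulate_gaussian(
    cfg: GaussianSimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, dict[float, ScoredLabels]]:
    """Draw states, annotate with a noisy first assessment, re-assess.

    Returns the per-gene annotation labels and, for each assessment sigma,
    a ``ScoredLabels`` pairing re-assessment scores with those fixed labels.
    The re-assessment is independent of the annotating assessment; across
    sigma levels it shares a single standard-normal draw per gene (common
    random numbers), so raising sigma acts as a pure noise dial and the
    resulting AUROC is non-increasing in sigma along every sample path.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    means = np.asarray(cfg.state_means, dtype=float)
    states = rng.choice(means.size, size=cfg.n_genes, p=cfg.mixing_proportions)
    mu = means[states]

    ann_scores = mu + cfg.annotation_sigma * rng.standard_normal(cfg.n_genes)
    labels = (ann_scores > cfg.annotation_threshold).astype(int)
    if labels.sum() in (0, cfg.n_genes):
        raise ValueError("degenerate annotation: all genes on one side of the threshold")

    ids = [f"g{i}" for i in range(cfg.n_genes)]
    z = rng.standard_normal(cfg.n_genes)
    assessments = {
        float(sigma): ScoredLabels(ids, mu + sigma * z, labels)
        for sigma in cfg.assessment_sigmas
    }
    return labels, assessments


@dataclass
class NetworkSimConfig:
    """Configuration of the block-structured network model.

    ``within_means`` gives the mean edge weight inside each community (a
    scalar applies to all); between-community weights are
    N(between_mean, between_sd).  ``annotation_probs`` is the per-community
    probability that a gene is annotated.  Negative weight draws are
    clipped to 0 so the matrix is a valid non-negative network.
    """

    n_genes: int = 10_000
    n_communities: int = 4
    community_size: int = 2_500
    annotation_probs: Sequence[float] = (0.8, 0.1, 0.1, 0.1)
    between_mean: float = 2.0
    between_sd: float = 2.0
    within_means: float | Sequence[float] = (2.0, 2.1, 2.2, 2.3)
    within_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities * self.community_size != self.n_genes:
            raise ValueError("n_communities * community_size must equal n_genes")
        if np.isscalar(self.within_means):
            self.within_means = (float(self.within_means),) * self.n_communities
        if len(self.within_means) != self.n_communities:
            raise ValueError("within_means must give one mean per community")
        if len(self.annotation_probs) != self.n_communities:
            raise ValueError("annotation_probs must give one probability per community")
        if not all(0 <= p <= 1 for p in self.annotation_probs):
            raise ValueError("annotation probabilities must lie in [0, 1]")


NETWORK_ANNOTATION_PRESETS: dict[str, tuple[float, ...]] = {
    "non_modular": (0.5, 0.5, 0.5, 0.5),
    "on_off": (0.8, 0.1, 0.1, 0.1),
    "on_low_off": (0.8, 0.5, 0.1, 0.1),
    "continuous": (0.4, 0.3, 0.2, 0.1),
}


def network_preset(name: str, **overrides) -> NetworkSimConfig:
    if name not in NETWORK_ANNOTATION_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(NETWORK_ANNOTATION_PRESETS)}"
        )
    return NetworkSimConfig(
        **{"annotation_probs": NETWORK_ANNOTATION_PRESETS[name], **overrides}
    )


def simulate_network(
    cfg: NetworkSimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[WeightedNetwork, AnnotationMatrix]:
    """Sample a block-model weighted network and one annotation set.

    Each unordered gene pair gets a single Gaussian draw mirrored to both
    matrix entries; diagonal entries come from the within-community
    distribution.  Labels are per-community Bernoulli draws.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    comm = np.repeat(np.arange(cfg.n_communities), cfg.community_size)

    mean = np.full((n, n), cfg.between_mean)
    sd = np.full((n, n), cfg.between_sd)
    same = comm[:, None] == comm[None, :]
    within_mean = np.asarray(cfg.within_means)[comm]
    mean[same] = np.broadcast_to(within_mean[:, None], (n, n))[same]
    sd[same] = cfg.within_sd

    draws = mean + sd * rng.standard_normal((n, n))
    upper = np.triu(draws)
    w = upper + np.triu(draws, k=1).T  # one draw per pair, mirrored
    np.clip(w, 0.0, None, out=w)

    ids = [f"g{i}" for i in range(n)]
    probs = np.asarray(cfg.annotation_probs)[comm]
    labels = (rng.random(n) < probs).astype(int)
    ann = AnnotationMatrix(ids, ["simulated_function"], labels[:, None])
    return WeightedNetwork(ids, w), ann
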