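"""Network preparation: propagation, TF-IDF cosine, top-fraction cut.

Builds a toy sparse interaction network and densifies it with inverse
shortest-path propagation; builds a protein-domain one-hot matrix and turns
it into a similarity network via TF-IDF cosine; thresholds a score matrix
to its top decile of interactions.
"""

import numpy as np

import rocfec
from rocfec.netprep import OneHotFeatures

rng = np.random.default_rng(0)

# sparse interaction network -> dense inverse-hop-distance weights
n = 30
w = (rng.random((n, n)) < 0.08).astype(float)
w = np.maximum(w, w.T)
np.fill_diagonal(w, 0)
net = rocfec.WeightedNetwork([f"g{i}" for i in range(n)], w)
dense = rocfec.shortest_path_propagation(net)
print(f"sparse density {w.mean():.2f} -> propagated nonzero fraction "
      f"{(dense.weights > 0).mean():.2f}; weights are 1/hops in [0, 1]")

# protein-domain one-hot -> TF-IDF cosine similarity network
ind = (rng.random((8, 5)) < 0.4).astype(float)
ind[ind.sum(axis=1) == 0, 0] = 1
sim = rocfec.tfidf_cosine(OneHotFeatures([f"p{i}" for i in range(8)],
                                         [f"d{j}" for j in range(5)], ind))
print(f"domain-similarity network: mean off-diagonal similarity "
      f"{sim.weights[~np.eye(8, dtype=bool)].mean():.2f} "
      "(rare shared domains weigh more than common ones)")

# real-valued interaction scores -> top-10% binary interactions
scores = rng.random((100, 6))
binary = rocfec.top_fraction_binarize([f"p{i}" for i in range(100)],
                                      [f"drug{j}" for j in range(6)],
                                      scores, fraction=0.1, min_items=5)
print(f"top-decile cut keeps {int(binary.indicator.sum())} of "
      f"{scores.size} interactions across {len(binary.feature_ids)} features")
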