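"""Neighbor-voting modularity of an annotated gene set on a block network.

Simulates a 4-community weighted network whose within-community mean edge
weight is dialed up from the between-community level (no modularity) to a
clearly modular regime, annotates one community's function probabilistically,
and scores the annotation with 3-fold cross-validated neighbor voting.
"""

import numpy as np

import rocfec

print("mu_within  mean AUROC (5 seeds)")
for mu in (2.0, 2.1, 2.2, 2.3):
    aurocs = []
    for seed in range(5):
        cfg = rocfec.network_preset("on_off", n_genes=2000, community_size=500,
                                    within_means=mu, seed=seed)
        net, ann = rocfec.simulate_network(cfg)
        aurocs.append(rocfec.egad_cv(net, ann, "simulated_function",
                                     seed=seed).mean_auroc)
    print(f"   {mu:.1f}       {np.mean(aurocs):.3f}")
print("At mu_within = 2.0 the network carries no community signal and the")
print("AUROC sits at chance; it rises steadily with the observed modularity.")
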