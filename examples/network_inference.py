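"""Group-specific regulatory networks by per-feature Random LASSO.

Each feature is regressed on all others, separately per survival group;
row i of the adjacency matrix holds feature i's regression coefficients.
Recovery is scored on the undirected edge skeleton.
"""

import numpy as np

import omicsig as og

cfg = og.SimConfig(n_samples=400, features_per_layer={"mRNA": 30},
                   network_density=0.1, de_fraction=0.0, seed=0)
cohort, truth = og.simulate_cohort(cfg)

rl = og.RandomLassoConfig(b1=100, b2=100, seed=0)
B_T, B_C = og.infer_group_networks(cohort.layers["mRNA"],
                                   cohort.group_labels(), rl)

for adj in (B_T, B_C):
    r = og.edge_recovery(adj.B, truth.true_network["mRNA"])
    print(f"group {adj.group_label!r}: precision {r['precision']:.2f}, "
          f"sensitivity {r['sensitivity']:.2f} "
          f"({r['tp']} true edges found, {r['fp']} spurious)")

edges = og.differential_edges(B_T, B_C, delta_threshold=0.1)
print(f"{len(edges)} edges differ between groups by |delta| >= 0.1")
print(edges.head(3).to_string(index=False))

# Both groups share the same generating network here, so the differential
# edge list reflects only estimation noise; on real cohorts it ranks
# candidate group-specific rewiring.
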