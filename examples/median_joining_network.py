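"""Median-joining network of a star-like expansion.

A founder haplotype with eight single-step derivatives — the signature of
a recent population expansion — yields a founder-centred star with no
inferred median nodes.  A second toy with three mutually two-step
haplotypes shows a median (Steiner) node shortening the network.
"""

import numpy as np

from ystrkit import median_joining, preprocess_network_input
from ystrkit.network import NetworkInput
from ystrkit.simulate import star_expansion_table

table = star_expansion_table(n_offspring=8, founder_multiplicity=5)
net = median_joining(preprocess_network_input(table, weights=1.0))
print("Star expansion:")
print(net.nodes_table().sort_values("multiplicity", ascending=False).head())
print(f"edges: {net.graph.number_of_edges()}, "
      f"median nodes: {len(net.median_nodes())}, "
      f"total length: {net.total_length:.0f} mutational steps")

inp = NetworkInput(
    ("L1", "L2", "L3"),
    [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    [1, 1, 1],
    np.ones(3),
)
net2 = median_joining(inp)
print(
    f"\nDisjoint-difference toy: {len(net2.median_nodes())} median added, "
    f"total length {net2.total_length:.0f} (the spanning tree without it "
    "needs 4 steps)."
)
print(
    "\nMedian nodes are unsampled intermediate haplotypes the algorithm "
    "infers when\nthey shorten the overall network."
)
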