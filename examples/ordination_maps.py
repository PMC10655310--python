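"""Classical MDS of a distance matrix and PCA of haplogroup frequencies.

Simulates five island populations, embeds their pairwise Fst matrix in
two dimensions with metric MDS, and decomposes the haplogroup frequency
matrix by PCA — the two low-dimensional maps typically drawn in
population comparisons.
"""

import numpy as np

from ystrkit import classical_mds, haplogroup_frequencies, pairwise_fst, pca
from ystrkit.popgen import DistanceMatrix
from ystrkit.simulate import island_model_haplogroups

groups = island_model_haplogroups(n_populations=5, n=80, theta=0.08, seed=7)
dm = pairwise_fst(groups, permutations=0)
clipped = np.clip(dm.values, 0, None)
np.fill_diagonal(clipped, 0.0)

mds = classical_mds(DistanceMatrix(dm.labels, clipped), k=2)
print("MDS coordinates (populations close together are genetically similar):")
print(mds.coordinates.round(4))

freqs = haplogroup_frequencies(groups)
res = pca(freqs)
print("\nPCA scores on the haplogroup frequency matrix:")
print(res.coordinates.iloc[:, :2].round(4))
print(
    "\nPC1 and PC2 carry "
    f"{100 * res.variance_fractions[:2].sum():.1f}% of the variance "
    f"(PC1 = {100 * res.variance_fractions[0]:.1f}%, "
    f"PC2 = {100 * res.variance_fractions[1]:.1f}%)."
)
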