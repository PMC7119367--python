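"""Localize donor-like codon usage with a 10-gene sliding-window PCA.

Every window of 10 consecutive genes becomes a 59-dimensional vector of
within-family synonymous codon proportions; PCA of the windows separates
island genes (donor codon usage) from the host background.
"""

import numpy as np

from hgtscan import gene_window_vectors, run_pca
from hgtscan.simulate import IslandSpec, SimulationSpec, simulate_genome

sim = simulate_genome(
    SimulationSpec(
        seed=3,
        genome_bp=300_000,
        background_gc=0.60,
        islands=[IslandSpec(length_bp=70_000, gc=0.50)],
    )
)

windows = gene_window_vectors(sim.genome, window_genes=10)
result = run_pca([v for _, v in windows], [w.name for w, _ in windows])
evr = result.explained_variance_ratio
print(f"{len(windows)} windows; PC1 explains {100 * evr[0]:.1f}% of variance")

island = sim.truth.islands[0]
inside = np.array(
    [island.start <= w.start and w.end <= island.end for w, _ in windows]
)
pc1 = result.scores[:, 0]
print(f"mean PC1: island windows {pc1[inside].mean():+.3f}, "
      f"background {pc1[~inside].mean():+.3f}")
# The two means sit on opposite sides of zero: the island's shifted codon
# usage is linearly separable from the host along the first component.
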