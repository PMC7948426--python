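"""Spot spatially conserved residue positions across superposed structures.

Generates eight jittered copies of a frame containing two planted consensus
sites (with two genes contributing twice, i.e. redundantly) plus random
decoys, then runs two-round consensus clustering: cluster at a 1.5 Å
linkage cutoff, keep one member per gene within each cluster, re-cluster,
and report clusters with at least five members.
"""

import numpy as np

from protonsense import EnsembleSpec, LabeledPoint, make_ensemble, two_round_cna
from protonsense.phinder_core import ionizable_sites

spec = EnsembleSpec(
    seed=11,
    n_structures=8,
    genes=["G1", "G1", "G2", "G3", "G4", "G5", "G6", "G6"],
    consensus_sites=np.array([[0.0, 0.0, 0.0], [14.0, 6.0, -4.0]]),
    jitter_sd=0.3,
    decoy_rate=3.0,
)
models, manifest, truth = make_ensemble(spec)

points = [
    LabeledPoint(s.reference_point, m.structure_id, m.gene_label, s.residue_name)
    for m in models
    for s in ionizable_sites(m)
]
print(f"pooled {len(points)} residue positions from {len(models)} structures")

clusters = two_round_cna(points, cutoff=1.5, min_size=5)
print(f"consensus clusters (cutoff 1.5 A, min size 5): {len(clusters)}")
for i, c in enumerate(clusters):
    x, y, z = c.centroid
    print(f"  cluster {i}: {c.size} members from {len(c.genes)} genes, "
          f"centroid ({x:+.2f}, {y:+.2f}, {z:+.2f})")
print("""
Each planted site is recovered as one cluster whose size equals the number
of distinct genes (6, not 8): the second round counts a redundantly
represented gene once, so a single over-represented receptor cannot fake a
consensus. Decoys, scattered far apart, never reach the minimum size.""")
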