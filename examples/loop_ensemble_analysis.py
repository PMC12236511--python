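"""Ensemble statistics for a two-state gating loop: RMSF and minimum
inter-residue distance distributions.

Generates a 20-conformation ensemble of a decamer-like assembly whose
loop (residues 9-14 of each chain) hops between a closed and an open
position, then measures per-residue RMSF (aligning on the rigid residues
so loop motion is not absorbed into the fit) and the per-chain minimum
distance between the loop tip and a rigid probe residue, summarised by a
Scott-bandwidth KDE and a 150-bin histogram.
"""

import numpy as np

from loopstate import geometry as G
from loopstate.structures import AtomSelection
from loopstate.synthetic import LoopEnsembleConfig, gen_loop_ensemble

CHAINS = "ABCDEFGHIJ"

config = LoopEnsembleConfig(seed=21)  # occupancy 0.5, displacement 21 A
ensemble, truth = gen_loop_ensemble(config)

align = AtomSelection.parse(
    ",".join(f"{c}:1-8" for c in CHAINS) + ","
    + ",".join(f"{c}:15-24" for c in CHAINS))
report = AtomSelection.parse(",".join(f"{c}:9-14" for c in CHAINS))
profile = G.rmsf(ensemble, align, report)

expected = truth["expected_loop_rmsf"][11]
print(f"loop RMSF (max over residues): {profile.max():.2f} A")
print(f"two-state expectation d*sqrt(p(1-p)) (+jitter): {expected:.2f} A")

pp = truth["probe_pair"]
dist = G.min_distance_distribution(ensemble, pp["residueA"], pp["residueB"])
print(f"min-distance samples: {dist.samples.shape[0]} conformations x "
      f"{dist.samples.shape[1]} chains")
print(f"closed/open construction distances: {pp['d_closed']:.2f} / "
      f"{pp['d_open']:.2f} A")
counts, edges = dist.hist_counts, dist.hist_edges
print(f"histogram: {counts.sum()} counts in {len(counts)} bins "
      f"spanning [{edges[0]:.2f}, {edges[-1]:.2f}] A")
print(f"KDE integral: {np.trapezoid(dist.kde_density, dist.kde_grid):.4f}")
print()
print("A loop RMSF above 10 A signals a broad open ensemble; the bimodal")
print("distance distribution splits its mass between the closed-contact")
print("and open distances in proportion to the state occupancy.")
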