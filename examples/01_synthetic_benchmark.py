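"""Generate a synthetic PPI benchmark with planted disease signal.

Builds a scale-free interaction network, plants a connected 25-gene module
whose genes carry shifted differential-expression z-scores, marks the
module's hub genes as "known biomarkers", and draws case/control expression
with per-gene effect sizes.
"""

import numpy as np

import netmark as nm

config = nm.SyntheticConfig(seed=7)
sim = nm.simulate(config)

print(f"network: {sim.network.number_of_nodes()} nodes, "
      f"{sim.network.number_of_edges()} edges")
degrees = [d for _, d in sim.network.degree()]
print(f"degree distribution: max {max(degrees)}, median {int(np.median(degrees))} "
      "(heavy-tailed, as in real PPI networks)")

planted = sim.de_table.loc[sorted(sim.truth.module_nodes)]
print(f"planted module: {len(sim.truth.module_nodes)} genes, "
      f"mean z = {planted['zscore'].mean():.2f} (background mean ~0)")
print(f"known biomarkers planted at module hubs: {len(sim.truth.biomarker_nodes)}")
print(f"expression: {sim.expression.shape[0]} genes x {sim.expression.shape[1]} samples "
      f"({(sim.sample_labels == 'case').sum()} cases / "
      f"{(sim.sample_labels == 'control').sum()} controls)")
print("biomarker genes carry a mean shift giving a theoretical "
      "single-gene diagnostic AUC of 0.9.")
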