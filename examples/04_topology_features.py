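"""The 11-node-topology feature battery.

Shows the full feature vector of a star center (an extreme hub) and of a
Petersen-graph node (a perfectly regular position), and the battery on a
small disease subnetwork.
"""

import networkx as nx

import netmark as nm

star = nx.relabel_nodes(nx.star_graph(6), str)
features = nm.compute_features(star)
print("star-graph center (hub archetype):")
print(features.loc["0"].to_string(float_format=lambda v: f"{v:.3f}"))
print("stress counts shortest paths through the node (all 15 leaf pairs); "
      "betweenness is the same quantity normalized per component pair.\n")

petersen = nm.compute_features(nx.relabel_nodes(nx.petersen_graph(), str))
assert (petersen.nunique() == 1).all()
print("Petersen graph: all 10 nodes share one feature vector "
      "(vertex-transitivity check):")
print(petersen.iloc[0].to_string(float_format=lambda v: f"{v:.3f}"))
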