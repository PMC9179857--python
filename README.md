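# netmark

Network-topology machine learning for prioritizing diagnostic protein
biomarkers on protein–protein interaction (PPI) networks.

Disease-associated proteins cluster on interaction networks, and known
diagnostic biomarkers tend to occupy distinctive topological positions —
often hubs of the disease-specific region.  `netmark` turns that
observation into a testable pipeline for systems-biology researchers:

1. **Differential expression** — a moderated t-test (empirical-Bayes
   variance squeeze) on a genes × samples matrix; DEGs are the genes with
   *p* < 0.05 and |log2FC| > 1.
2. **Active subnetwork** — p-values become z-scores, *z* = Φ⁻¹(1 − *p*);
   a subnetwork *A* with *k* nodes scores *z(A)* = (1/√k) Σ_{i∈A} z_i, and a
   multi-restart greedy search extracts the highest-scoring connected
   module; high-z genes plus their best neighbors induce the
   disease-specific subnetwork.
3. **Topology features** — eleven per-node statistics (degree, average
   shortest path length, closeness, betweenness, stress, eccentricity,
   clustering coefficient, neighborhood connectivity, number of directed
   edges, radiality, topological coefficient).
4. **Model** — a CART tree selects the informative features; a soft-margin
   SVM with one of eight kernels (linear, polynomial, RBF, Laplacian, tanh,
   Bessel, ANOVA-RBF, spline) learns known-biomarker vs non-biomarker
   nodes; Platt scaling turns decisions into an "SVM point" (probability of
   being a biomarker), and nodes with point ≥ 0.99 become candidates.
5. **Verification** — rank-statistic ROC/AUC with explicit score
   orientation (down-regulated markers are flagged, not hidden), logistic
   multi-biomarker panels, and recovery metrics against planted truth.

A synthetic benchmark generator (scale-free network, planted high-z module,
hub-placed biomarker labels, binormal case/control expression with
closed-form per-gene AUC) makes every stage testable end to end without any
downloads.

## Worked example

```python
import netmark as nm

sim = nm.simulate(nm.SyntheticConfig(n_nodes=2000, module_size=25,
                                     signal_mean=3.0, seed=11))
network = nm.filter_by_confidence(sim.network, 0.7)
zmap = nm.zmap_from_table(sim.de_table)

result = nm.greedy_module_search(network, zmap, iterations=10, max_size=30)
overlap = result.nodes & sim.truth.module_nodes
print(result.k, round(result.score, 2), len(overlap))
```

prints `30 15.32 21`: the greedy search returns a 30-gene module with
Stouffer score z(A) = 15.32 — a standard-normal score under the null, so
overwhelming evidence of a coherent active region — that recovers 21 of the
25 planted module genes (Jaccard 0.62).

Running the whole pipeline on the shipped defaults
(`python examples/07_full_pipeline.py`, or `netmark run`) ends with

```
planted-biomarker recovery over 465 scored nodes:
  point-score AUC 0.866  precision@16 = 0.25 (prevalence 0.032)
best single-gene diagnostic AUC among top-ranked candidates: 0.897
logistic multi-biomarker panel AUC: 0.897
```

i.e. the SVM point ranks planted biomarkers far above chance (precision ~8×
prevalence), the best candidate gene separates cases from controls with
AUC ≈ 0.9 (its planted effect size targets exactly that), and the logistic
panel combines candidates into a single diagnostic score.

Each script in `examples/` demonstrates one capability (synthetic
benchmark, DE, module search, topology battery, kernel SVM, ROC/panels,
full pipeline) and prints what the numbers mean.  The `netmark` command
exposes the same stages as subcommands (`simulate`, `de`, `module`,
`features`, `train`, `predict`, `evaluate`, `recover`, `run`); see
`docs/methods.md` for the full model description and defaults.

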