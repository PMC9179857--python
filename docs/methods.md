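# Methods

`netmark` implements a network-topology machine-learning workflow for
prioritizing diagnostic protein biomarkers on protein–protein interaction
(PPI) networks: differential-expression (DE) filtering → Stouffer-Z active
subnetwork extraction → an 11-feature node-topology battery → tree-based
feature selection → a multi-kernel SVM with probability calibration →
ROC verification and logistic multi-biomarker panels.  This note records the
model, the defaults and why, the numerics, and the limits of what the
synthetic benchmark can show.

## Differential expression

Inputs are assumed pre-normalized log2-scale expression values, so the
log2 fold change of gene *g* is the case-minus-control group mean.  The test
is the standard empirical-Bayes moderated t: gene-wise pooled variances
`s²_g` (residual df `d = n₁ + n₂ − 2`) are squeezed toward a prior,

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),

with `(d₀, s₀²)` estimated by the method of moments on `log s²_g`
(digamma/trigamma inversion), and `t = lfc / (s̃ √(1/n₁ + 1/n₂))` referred
to `t_{d+d₀}`.  Setting the prior df to 0 recovers the ordinary pooled
t-test exactly (verified against `scipy.stats.ttest_ind`); with estimated
prior df the p-values agree with limma's `lmFit + eBayes` to ~1e-15 on a
frozen fixture.  A variance floor of 1e-12 guards zero-variance genes.

DEG filtering is deliberately strict-inequality on raw p-values:
`p < 0.05` **and** `|log2FC| > 1`.  No multiple-testing correction enters
the filter; a Benjamini–Hochberg column is emitted for information only.

## Active subnetwork (Stouffer-Z greedy search)

Each p-value maps to `z = Φ⁻¹(1 − p)` (clamped to `[1e-16, 1 − 1e-16]`), so
stronger DE evidence means larger z.  A connected subnetwork `A`, `|A| = k`,
scores

    z(A) = (1/√k) Σ_{i∈A} z_i        ("stouffer", default)

which is standard normal for fixed `A` under the global null.  A "mean"
normalization `(1/k) Σ z_i` is available by configuration; it is not the
default because the mean score cannot reward evidence accumulation — it
degenerates toward the single best gene — while the √k form is the
normalization of the classical active-module (jActiveModules-style) greedy
search this stage mirrors.  Background correction and simulated annealing
variants of that method are intentionally not implemented.

The search runs `iterations` (default 10) greedy restarts, one from each of
the highest-z distinct seed nodes; each restart repeatedly adds the
neighboring node that maximally increases z(A) (for both normalizations
this is the max-z frontier node), stopping when no neighbor improves the
score or `max_size` (default 30) is reached.  Ties break lexicographically
by node id, so the procedure is fully deterministic.  Genes without a
p-value are imputed at z = 0 (p = 0.5), neutral under both normalizations.
Edges with confidence ≤ 0.7 are dropped before the search; confidences do
not otherwise weight the score.

The disease-specific subnetwork ("CCS" in the code/config) is the subgraph
induced by all genes with `z > z_threshold` plus, for each, its single
highest-z neighbor.  The threshold has no canonical value; the shipped
default is 1.0, which on the default benchmark yields a ~450-node subnetwork
whose giant component contains the planted module (2.0 left a fragmented
~100-node graph too small to train on).

## Topology battery

Eleven per-node statistics, computed on unweighted hops per connected
component, following NetworkAnalyzer-style conventions.  For node *v* with
degree `k(v)`, neighbors `N(v)`, distances `d`, shortest-path counts `σ_st`
and `σ_st(v)`:

| feature | definition |
|---|---|
| degree | `k(v)` |
| average shortest path length | mean `d(v, w)` over reachable `w` |
| closeness | `1 / asp(v)` (0 for isolated nodes) |
| betweenness | `Σ σ_st(v)/σ_st` over unordered pairs `s ≠ v ≠ t`, normalized by `(n−1)(n−2)/2` of the component |
| stress | `Σ σ_st(v)` over the same pairs (raw path count) |
| eccentricity | max `d(v, w)` |
| clustering coefficient | `2 e(v) / (k(k−1))`, 0 if `k < 2` |
| neighborhood connectivity | mean degree of `N(v)` |
| number of directed edges | incident-edge count — equal to degree on a simple undirected graph, kept only for fidelity to the conventional 11-feature list |
| radiality | `(Δ_C + 1 − asp(v)) / Δ_C`, `Δ_C` the component diameter; 1.0 when `Δ_C = 0` |
| topological coefficient | `mean_{m∈S(v)} J(v,m) / k(v)`; `S(v)` = nodes ≠ v sharing ≥ 1 neighbor, `J = |N(v) ∩ N(m)|` + 1 if v–m is an edge; 0 when `k ≤ 1` or `S = ∅` |

Betweenness and stress are accumulated in one Brandes-style BFS sweep per
source (O(V·E) per component) and validated feature-by-feature against a
brute-force path-enumeration oracle on random graphs and on star / cycle /
complete / Petersen fixtures (exact for integer features, 1e-9 otherwise).

## Feature selection (CART)

A Gini-split classification tree (a squared-error regression tree on the
0/1 target by configuration — the contract is the selected-feature set, not
the impurity flavor) is grown on the training partition with
`min_samples_split = 20` and the rpart `minbucket = round(minsplit/3)` leaf
floor, then pruned by weakest-link cost-complexity on **misclassification
risk** relative to the root (threshold `complexity × risk(root)`, default
complexity 0.01).  Misclassification-based pruning, not the split
criterion, is what makes a stump reachable at all on weak data; the gini
based `ccp_alpha` of scikit-learn prunes almost nothing at comparable
settings.  The selected features are the distinct split features of the
pruned tree, root first.  If the tree prunes to a stump the caller falls
back to the full 11-feature battery with a warning.  Note that on pure-noise
labels a CART split almost always removes at least one training
misclassification, so stumps on noise require a pruning threshold of
roughly 0.3 — at the 0.01 default a noise tree usually keeps a spurious
split, exactly as rpart does without cross-validation pruning.

## Kernel SVM and the SVM point

Training rows are z-standardized (train-set mean/sd only; prediction reuses
the stored parameters — no leakage), then a soft-margin C-SVC (C = 1 by
default) is solved on the precomputed Gram of one of eight kernels: linear,
polynomial, RBF, Laplacian, hyperbolic tangent, Bessel, ANOVA-RBF, spline
(definitions in `netmark.kernels`; values verified against R kernlab to
1e-9).  The Bessel kernel is normalized by its `r → 0` limit
`L = 1/(Γ(ν+1) 2^ν)` so `k(x, x) = 1` exactly, with the removable
singularity evaluated as 1 below `σr < 1e-5`.  Kernel parameters default to
σ = 1, degree = 1, ν = 1, scale = 1, offset = 1 — ordinary toolkit
defaults, all exposed in configuration, none tuned.

tanh, Bessel and spline Grams can be indefinite; the standard workaround is
applied: training clips negative Gram eigenvalues to zero before the QP,
while prediction evaluates the unclipped kernel against the stored support
vectors.

Decision values are mapped to probabilities ("SVM points") by Platt scaling
with target smoothing (`t₊ = (N₊+1)/(N₊+2)`, `t₋ = 1/(N₋+2)`), fit by a
damped Newton iteration on the cross-entropy.  Candidates are the nodes
whose point reaches the cutoff (default 0.99, a configuration constant),
excluding already-known biomarkers, ranked by point with lexicographic tie
breaks.  Kernel comparison reports test-partition AUC of raw decision
values — AUC is invariant to the monotone Platt map, and the AUC is *not*
orientation-flipped there, so a kernel that ranks classes backwards shows
below 0.5.

## ROC, orientation, and panels

AUC is the rank statistic `U/(n₁n₀)` with ties credited ½ (equal to the
trapezoidal area of the step ROC; verified against explicit pairwise
counting to 1e-12).  Score orientation is explicit: if the raw AUC is below
0.5 the score is flipped, the flipped AUC reported, and
`orientation = lower_is_case` recorded — never silent, because
loss-of-expression markers are genuinely diagnostic with lower values in
disease.  Panels fit a maximum-likelihood logistic regression by IRLS
(tolerance 1e-8, ≤ 100 iterations); on separation or non-convergence the
fit retries with a weak ridge (1e-6, intercept unpenalized) rather than
refusing, since perfectly separating synthetic panels are expected.

## Synthetic benchmark: what it emulates, and what not

The generator stands in for the three real inputs (a String-style
high-confidence PPI network, portal-derived DE statistics, a case/control
expression cohort) with planted ground truth:

- **Network** — preferential attachment: a path on `m` seed nodes, then
  each new node attaches to `m = 2` distinct degree-weighted targets
  (edge count `(m−1) + (n−m)·m`; 2000 nodes / 3997 edges by default).
  Edge confidences are Beta(5, 1) rescaled to (0.7, 1.0], respecting the
  confidence > 0.7 filter.
- **DE signal** — a connected 25-gene module grown with *degree-biased*
  frontier sampling carries `z ~ N(signal_mean = 3, 1)` against an `N(0,1)`
  background; `p = 1 − Φ(z)`; planted |log2FC| uniform on [1.2, 3] (random
  sign) so planted genes pass the DEG filter, background log2FC ~ N(0, 0.5)
  so few do.  Degree-biased growth matters: a uniformly grown module avoids
  hubs, leaving planted biomarkers with no topological signature to learn.
- **Biomarker labels** — the module's 16 highest-degree genes by default
  (a "random placement" switch exists).  16 labeled positives put ~22 rows
  in the training partition at the default 0.7 split, comparable to a
  22-versus-22 known-biomarker training design and above the tree's
  `minsplit`.
- **Expression** — gene *g* is `N(δ_g, σ)` in cases, `N(0, σ)` in controls
  (σ = 1), so the single-gene ROC AUC has the closed form `Φ(δ_g/(σ√2))`.
  Default effect sizes target AUC 0.9 for biomarker genes and 0.75 for the
  other module genes; background genes carry none.  Cohort sizes default to
  275 cases / 349 controls.

Not emulated: interaction evidence channels, probe/platform structure,
gene–gene expression correlation (genes are independent given labels),
survival times, and any coupling between a gene's DE z-score and its
expression effect size beyond module membership.  Passing tests therefore
demonstrate correctness of the machinery and recoverability of a planted
signal under idealized noise — not performance on real cohorts.

## Pipeline, determinism, and problem sizes

`run_pipeline` executes eight stages (simulate/load, DE filter, module +
subnetwork, features, labeled-set + selection, SVM training + kernel
comparison, candidate prediction, evaluation), writing each artifact as
plain text plus a manifest (config hash excluding the output path, derived
stage seeds, per-stage counts).  All randomness derives from the single
top-level seed via a seeded generator, so identical configurations
reproduce byte-identical TSVs.  By default every subnetwork node is scored
("universe: ccs"); "universe: degs" restricts scoring to DEG nodes, the
choice matching a real-data screen where only DE proteins are candidates —
under the generator's sparse background-DEG regime that universe is a
handful of nodes and nearly half planted, which makes enrichment metrics
meaningless, hence not the default.

Default problem sizes (2000-node network, 25-gene module, 472-node
subnetwork, 624-sample cohort, 10,000 null subsets for calibration) keep a
full run in a few seconds and the whole test suite under a minute while
leaving every estimate comfortably inside its tolerance; they are stated in
the test/docstrings wherever they matter.

## Known limitations

- The greedy search returns a single best module; overlap-constrained
  multiple-module reporting is out of scope.
- Exact betweenness/stress only — fine at subnetwork scale, quadratic
  beyond ~10⁴ nodes.
- The 0.99 point cutoff is a convention, not an estimated threshold; with
  small calibration sets the smoothed Platt targets cap fitted
  probabilities near `(N₊+1)/(N₊+2)`, so few or no candidates may clear it
  (the ranking and its AUC are the robust outputs).
- The negative-control ("non-DE") sampler is seeded but arbitrary; there is
  no canonical draw to reproduce.
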