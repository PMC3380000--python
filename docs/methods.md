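# Methods

## Scope and data model

`clrnet` starts from an already-normalized log2 expression matrix
(probesets × samples) with a sample design table (condition, time,
replicate, baseline flag). Probe-level normalization (e.g. RMA from raw
array images) is upstream and out of scope; the loader validates structure
and finiteness only and never imputes. Probesets are treated as independent
network nodes throughout — several probesets may interrogate one gene, and
collapsing them (or picking a representative) would add its own
uncertainty to topology. Gene symbols enter only in gene-level operations:
enrichment, cross-network intersection, neighbor tables. Unannotated
probesets ride through the network stages under their probe id and drop
out of gene-level steps with a logged count.

## Differential filter

Per probe, a two-way ANOVA with condition and time as main effects
(no interaction). Two choices here are genuinely open and we fixed them as
follows:

- **Main effects only.** With n = 4 replicates per condition × time cell,
  a full interaction model spends most of its degrees of freedom on terms
  that cannot be estimated stably; the selection rule needs one omnibus
  p-value per probe, not per-cell contrasts.
- **Baseline controls are excluded from the ANOVA fit.** Untreated
  controls occupy no condition × time cell of the factorial; they serve as
  the reference for the fold-change criterion instead, which is the
  largest |mean log2 difference| of any condition × time group versus the
  mean of the baseline samples.

The omnibus F-test is computed from one shared QR decomposition of the
design matrix for all probes. Degenerate cases: zero total variance ⇒
p = 1 (no evidence); zero residual variance with real effects ⇒ p = 0.
Multiplicity is handled with the Benjamini–Hochberg step-up rule;
selection requires adjusted p < alpha (default 0.05) *and* fold change
≥ fc_threshold (default 2.0) on the log2 scale.

## Mutual information estimator

MI is estimated with fractional B-spline binning. `spline_order` k is the
B-spline *order* (polynomial degree k − 1); the default `bins = 10,
spline_order = 3` uses quadratic basis functions. Data are min–max
rescaled onto [0, bins − k + 1] with knot vector {0×k, 1, 2, …,
bins − k, (bins − k + 1)×k}, each observation contributing basis-function
weights (a partition of unity) to k adjacent bins. Marginal and joint
weighted histograms are normalized to probabilities and

    MI = Σ_{p(a,b) > 0} p(a,b) · ln [ p(a,b) / (p(a) p(b)) ]

in nats, clamped at 0. With k = 1 the scheme degenerates to ordinary hard
binning and reproduces the discrete plug-in estimator exactly — this is the
oracle used in the tests. A constant vector has no defined binning; its MI
is set to 0 with a logged warning (a constant carries no information, and
constants can survive the upstream filter on adjusted-p grounds in corner
cases). Unit choice (nats vs bits) cancels in the CLR z-scores.

The full MI matrix is computed by caching each probe's weight matrix and
forming joint histograms blockwise with `einsum`; the cost is
O(P² · bins² · samples) with ~50 MB of temporaries at the default block
size of 64 probes.

## CLR scoring and thresholding

For pair (i, j): z_i = (MI(i,j) − mean_i)/sd_i over row i's off-diagonal
MI values, using the **sample** (n − 1) standard deviation — one convention
had to be fixed for bit-reproducibility. Negative deviations are floored
at zero and z(i,j) = √(z_i² + z_j²). Rows with zero MI spread contribute
z = 0 (logged). Edges with z below the threshold are cut and isolated
nodes are dropped from the network, which records its threshold.

Threshold selection supports three modes:

- fixed `z_threshold`;
- `target_nodes`: the grid threshold whose surviving-node count is closest
  to the target (ties toward the larger, more conservative threshold);
- `match_nodes_to`: match a previously run network's node count. Here the
  anchor network's own threshold additionally breaks node-count ties:
  when the node-count curve plateaus (every probe keeps an edge over a
  whole threshold range, as happens on strongly modular data), every
  plateau point "matches" and plain tie-breaking toward the largest
  threshold would silently strip the weakest true edges; preferring the
  anchor's threshold keeps exchangeable networks at comparable density.

## Topology

Betweenness is computed with Brandes' algorithm on the **unweighted**
thresholded graph (CLR weights do not enter path lengths — the network
model treats an edge as a statistical association, not a distance), in the
unnormalized unordered-pair convention: each pair {s, t} contributes
σ_st(v)/σ_st once. Ranking, the only downstream consumer, is invariant to
the normalization constant, and the fixed convention makes the exhaustive
path-enumeration oracle exact. Betweenness is computed on the full,
possibly disconnected network; cross-component pairs contribute zero.
The top ceil(fraction · N) nodes (default fraction 0.2) are flagged as
bottlenecks, with boundary ties broken by node id so the flag set is
deterministic.

## Communities, enrichment, condensation

Louvain modularity optimization runs on the unweighted graph by default
(weighted optional), seeded for reproducibility; the reported modularity
is re-evaluated on the returned partition. Clusters of ≥ min_cluster_size
(default 10) probes are tested against every supplied gene-set term with
the exact hypergeometric upper tail P(X ≥ k), population = the gene
symbols of the network's own nodes (enrichment versus the rest of the
network, not the whole array), term sets intersected with that background
first. A per-cluster BH-adjusted p is reported alongside, but cluster
labels use the raw smallest-p term. The condensed graph has circle nodes
(bottlenecks) and square nodes (large clusters, labeled best term +
⌈−log10 p⌉); edge attribute `edge_type` distinguishes *membership* (the
bottleneck's own cluster) from *linkage* (a cluster containing at least
one of its network neighbors). Gene sets are taken as given in the GMT —
no ontology-graph propagation or term redundancy reduction.

## Cross-network comparison

Bottleneck probesets map to genes (set semantics: a gene is a bottleneck
in a network if any of its probesets is flagged); the conserved set is the
exact intersection. Its significance comes from a permutation null drawn
to condition on everything except the biology: for each network, a uniform
random gene set of that network's own bottleneck-set size from that
network's own node-gene universe; p = (1 + #{overlap ≥ observed}) /
(n_permutations + 1). The default 100 000 draws resolve p-values down to
1e-5 with acceptable Monte-Carlo error. All networks are assumed to share
a gene-symbol namespace (no ortholog mapping).

## Coherence test

Pearson correlations across the perturbation columns for all gene pairs;
r_in = mean over within-group pairs, r_out = mean over group × non-group
pairs. Pairs of two outside genes are excluded — the question is whether
the group coheres relative to its relationship with the outside, not how
the outside behaves internally. Significance is a Welch t test comparing
the two collections of pairwise correlations. Zero-variance genes are
excluded with a warning; a group reduced below two genes is an error.
With only one within-group pair the t statistic is undefined (reported as
NaN); r_in/r_out are still meaningful.

## Synthetic data generator

The generator emulates a designed multi-condition time-course study:
default 5 conditions × 5 time points × 4 replicates + 6 untreated baseline
controls, 5 modules × 40 genes, 6 bridge genes, 20 background genes, per-
sample Gaussian noise with sd 0.4 on a log2 baseline of 8. What it plants:

- **Module profiles** are additive condition-walk + time-walk surfaces
  over the condition × time grid — treatment and time effects combine the
  way the differential model expects, so planted signal is detectable by
  design. Raw surfaces are QR-orthogonalized against each other *and* the
  constant vector: independent walks on a 25-point grid can correlate
  strongly by chance, which would silently merge "distinct" modules.
  Each profile is scaled to sd 1.0 across the grid (spans ≈ 3–4.5 log2
  units, comfortably above the two-fold filter).
- **Bridge genes** average the profiles of two modules (equal weights).
  Equal profile sd makes a bridge correlate equally with both parent
  modules — the property that turns it into an inter-module connector and
  hence a true planted bottleneck. Bridge pairs are distinct (a ring
  through all modules, then chords), so each bridge is the sole planted
  connector of its module pair. A mixture whose span falls below 2.5 log2
  units is rescaled up to it: a planted bottleneck that cannot pass the
  fold-change filter would be unrecoverable by construction, and the floor
  leaves ≈ 1 standard error of margin on the estimated group means.
  Rescaling changes no correlation.
- **Background genes** are pure noise around the flat baseline; optional
  duplicate probesets replicate a gene with independent noise.
- The knockdown-response generator assigns each module a random subset of
  regulators; module genes share the module's latent effect per regulator
  plus noise, bridges average their modules' effects, background genes are
  noise only.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning (profile, noise, duplication, gene-set, knockdown streams), so
every artifact is bit-reproducible. Gene names are deterministic in the
parameters, so datasets generated with different seeds share planted
identities — that is what makes the multi-dataset conservation analysis
meaningful.

**Anchor threshold.** The CLR score scale depends on network size and
structure; on generator-scale networks (~200 probes with dense planted
modules) the score distribution is compressed relative to
compendium-scale networks with thousands of probesets, so thresholds
meaningful there are unattainable here. The declared anchor for synthetic
studies is z = 1.0 (`DEFAULT_SYNTHETIC_Z`): empirically just above the
null support of the score (background and cross-module pairs stay below
~1 at these sample sizes), so retained edges are overwhelmingly planted
structure. In the three-dataset benchmark, the first network uses the
anchor and the others are harmonized to its node count.

**What the benchmark shows — and does not.** Passing the synthetic
end-to-end recovery (bridge recall, cluster labels, conserved-bottleneck
significance) demonstrates that the pipeline's statistics do what they
claim on data with known ground truth at realistic design sizes and noise.
It does not demonstrate performance on real arrays: the generator has no
probe-level physics (hybridization, background, saturation), its modules
are cleaner and its class structure sharper than real coexpression, and
its noise is homoscedastic Gaussian. Real-data thresholds and the share of
probes surviving the differential filter will differ accordingly.

## Benchmark sizes and runtime

The shipped benchmark (`scripts/acceptance.py`, also exercised by the test
suite) uses the default generator conditions — 3 datasets × 226 probesets
× 106 samples — and 100 000 permutation draws; it completes in well under
a minute on one CPU. The pairwise-MI stage dominates and scales as
O(P² · samples), so compendium-scale inputs (thousands of selected
probesets) are feasible but take correspondingly longer.

## Known limitations

- The interaction-free ANOVA can miss probes whose response is purely
  condition × time interaction; such genes are invisible to the filter by
  design choice.
- CLR's background correction penalizes genes that are moderately
  correlated with many others (e.g. hubs spanning groups); their edges
  score lower than within-module edges, which is why threshold choice
  near the null support matters for connector recovery.
- The permutation null conditions on set sizes and universes but not on
  network topology; bottleneck sets are treated as exchangeable random
  draws under the null.
- Coherence pools dependent pairwise correlations into a t test; the
  p-value is a ranking heuristic more than a calibrated error rate.
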