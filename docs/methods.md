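# Methods

## The model

`ppiclust` treats each patient as a node-set-valued observation: the PPI
subnetwork induced by their most upregulated genes on a fixed reference
interactome. The analysis then reduces to (i) a distance between patients
(Jaccard on network element sets), (ii) hierarchical clustering of that
distance (UPGMA), (iii) an enrichment test per cluster (Fisher exact),
and (iv) graph-level summaries of interesting clusters (consensus
networks, hub ranking, and the separation score s_AB between two node
sets on the interactome).

### Interactome

The interactome is loaded once from a STRING-style edge list and
filtered at an evidence-score threshold (default 400, STRING's
conventional "medium confidence"; both the threshold and the score
column are configurable — when a file exposes several channels, an
experimental-evidence column can be selected by name). Duplicate records
collapse to the maximum score, self-loops are dropped, and nodes that
appear only in sub-threshold edges are excluded so that "gene maps to the
interactome" has a single meaning everywhere. All downstream distances
treat the surviving graph as unweighted: path length counts hops, and
evidence scores play no further role.

### Seeds and sample networks

Seeds are the top-k genes by expression z-score per patient, with ties
broken lexicographically so results are platform-independent. By default
the ranking is by signed z-score regardless of sign; a `positive_only`
switch restricts seeds to genes with z > 0 for cohorts where
"upregulated" should be taken literally. k defaults to 150; the
`select_seed_count` helper reruns the pipeline over a candidate grid
(e.g. 60–300) and reports the matrix of pairwise cophenetic correlations
between the resulting dendrograms, choosing the k with the highest mean
correlation to the others — a stability criterion — while always
emitting the full table so the user can override the choice.

Sample-network construction uses a maximum path length of 2: seed pairs
at distance 1 contribute their edge; pairs at distance 2 contribute
*every* intermediary on any shortest path (not one arbitrary path —
this keeps the construction order-independent), flagged as "imputed";
farther pairs contribute nothing. Because the graph is unweighted,
Dijkstra reduces to BFS and the implementation uses neighbourhood
intersections, verified in the tests against an exhaustive
all-pairs-BFS path enumeration oracle. Seeds with no qualifying
connection stay in the network as flagged isolated nodes (they carry
signal for the Jaccard distance); a switch drops them instead. Edges
among imputed nodes themselves are never added.

### Clustering and enrichment

The Jaccard distance defaults to node sets (seeds + imputed), the most
robust element universe; `edges` and `nodes+edges` modes are available
for sensitivity analysis. UPGMA is implemented directly (not via
scipy.cluster.hierarchy) for one reason: exact merge ties resolve by the
lexicographically smallest combined member set, a determinism guarantee
scipy does not make. On tie-free inputs the implementation agrees with
scipy's average linkage to machine precision, which the test suite
asserts. Heights use the d/2 convention (a leaf-to-root path has length
half the root's merge distance); cophenetic distances use the full merge
distance, so they match `scipy.cluster.hierarchy.cophenet` directly.

Every internal dendrogram node is a candidate cluster and receives a
two-sided Fisher exact p-value on the 2×2 table (in-cluster vs
out-of-cluster × case vs control), flagged at α = 0.05 with no
multiple-testing correction by default (an optional Benjamini–Hochberg
flag exists); raw p-values mirror how such cluster scans are usually
read, and the downstream selection rules only consume the flagged set. A
cluster is "dominated" by a group when it is significant and that
group's member fraction is at least 0.9 (configurable; the qualitative
notion of domination has no canonical number).

### Consensus networks and separation

A cluster's consensus network is the layered union of its members'
networks with per-node and per-edge sample counts; `min_fraction` prunes
nodes below a support threshold (default 0 = pure union). Node origin is
assigned relative to the opposing group's cluster: group-unique, shared,
or imputed — with seed status in *any* member overriding imputed status,
since direct seed evidence is stronger than path imputation. Hubs are
ranked by consensus degree, ties by sample count then id.

s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2 is computed on the full filtered
interactome, never within the consensus subgraphs. Within-set means use
each node's distance to the nearest *other* member of its set (hence
singleton sets are rejected with guidance); the cross term allows
distance 0 for nodes in both sets. Unreachable nodes are excluded from
the relevant mean and counted, rather than imputed with a pseudo-distance
(diameter + 1 was considered and rejected as distortionary).

For the cluster-level comparison the separation defaults to the
**group-unique** node sets of the two consensus networks
(`separation_nodes="unique"`), with `"full"` available. The full node
sets necessarily share background hubs, and every shared node contributes
a zero cross-distance, which drives s_AB negative whenever the networks
overlap at all; a positive separation between two recovered clusters is
only a meaningful claim about the group-specific parts of their
networks. With very large clusters even the unique sets can vanish (a
pure union over many members saturates the interactome); the comparison
then reports an explicit skip and suggests `consensus_min_fraction > 0`.

### Balancing

With heavily imbalanced cohorts, each of the (default 15) iterations
draws `controls_per_iter` controls uniformly without replacement —
default three times the case count, keeping per-run imbalance moderate
while sampling broadly across iterations — reruns the pipeline on
cases + sample, and harvests the significant cluster with the most
controls and fewer than two cases. Selected controls accumulate with set
semantics. Iteration i uses an independent RNG stream derived from
(master seed, i), so runs are reproducible end to end and byte-identical
given the same seed; case networks are built once and reused across
iterations.

## The synthetic-data generator

The generator emulates the pipeline's real inputs: a
preferential-attachment (Barabási–Albert, m = 3) background graph of
2,000 nodes by default, with one planted module per phenotype group —
50 genes wired internally at density 0.3 (connected by construction: a
random spanning tree filled to the target edge count) and attached to
the background by 2 bridge edges. Evidence scores are uniform on
400–1000 so the default confidence filter keeps every edge. Expression
is z[i, g] ~ Normal(δ·1[g ∈ module(group(i))], 1) with δ = 3 by
default: the simplest structure under which top-k ranking recovers
planted genes. Default group sizes are 29 cases / 965 controls,
mirroring a rare-phenotype cancer cohort of 994 patients; tests and the
acceptance script also use a 20/60 reduction with k = module size = 50,
which keeps replicate runs in the hundreds of milliseconds. Mutation
tables (driver/VUS classes over the seven MMR genes by default) exist
purely for frequency bookkeeping — percent of members with ≥1 qualifying
mutation, rounded to one decimal half-away-from-zero — and do not feed
back into expression.

What the generator does *not* emulate, and what passing tests therefore
do not show about real data: gene–gene expression correlation (real
z-scores are strongly correlated along pathways; synthetic background is
i.i.d. noise), RNA-seq count noise (inputs are already z-scores),
overlap between phenotype modules, and control heterogeneity. The last
point matters for the balancing workflow: because every synthetic
control shares one planted module, the control-dominated cluster in each
iteration legitimately contains essentially the whole control sample,
and the selected-control list grows toward the number of distinct
controls ever sampled — far more than the handful per iteration typical
of real, heterogeneous cohorts. The i.i.d. background also makes
pure-union consensus node sets grow faster with cluster size than
correlated real data would.

## Numerical and degenerate-input choices

- Jaccard is undefined when both element sets are empty → error.
- UPGMA validates symmetry, zero diagonal and the [0, 1] range; exact
  tie detection uses an absolute 1e-12 tolerance.
- Cophenetic correlation of two flat (zero-variance) trees is 1 when
  their distance vectors coincide, 0 otherwise.
- Fisher tests go through `scipy.stats.fisher_exact`; the test suite
  checks all 2×2 tables with N ≤ 25 against an exhaustive hypergeometric
  enumeration.
- Patients whose seed genes all fail to map are excluded with a warning,
  never silently.
- All public entry points that consume randomness take either a master
  seed or a `numpy.random.Generator`.

## Problem sizes used in the shipped tests

Oracle-equivalence suites run on 200 random graphs of ≤ 30 nodes
(network construction) and 50 of ≤ 20 nodes (separation); parameter
recovery uses five replicate 20/60 cohorts on 2,000-node interactomes;
the reproducibility check runs 5 balancing iterations on a 15/100
cohort; and the scale demonstration runs the full 29/965 cohort through
15 balancing iterations. These sizes were chosen so the entire suite
completes in well under a minute of compute per suite while still
exercising every code path at realistic shapes.

## Known limitations

- No permutation p-value for s_AB; the score is reported as a point
  estimate.
- No alternative linkages or bootstrap support on the dendrogram.
- The gene→protein map is identity by default; no orthology or alias
  resolution beyond an optional two-column mapping file.
- `--threads` is accepted for interface compatibility but execution is
  single-threaded; the pipeline's costs are small at the intended scales.
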