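# ppiclust

Multi-sample protein–protein-interaction (PPI) subnetwork clustering for
case/control cohorts.

Given (a) a reference interactome (a STRING-style edge list with evidence
scores), (b) a patient × gene expression z-score matrix, and (c) binary
phenotype labels, `ppiclust` identifies subgroups of patients that share
PPI network structure and asks whether those subgroups track the
phenotype. It was built for analyses such as distinguishing
mismatch-repair-(MMR-)deficient from MMR-intact tumors in large cancer
cohorts, where the phenotype of interest is rare (~3% of patients) and
per-patient molecular networks are more informative than single genes.

## Method

For each patient *i*:

1. **Seeds.** Take the *k* most upregulated genes by z-score
   (*k* = 150 by default; a cophenetic-correlation comparison across
   candidate *k* is provided).
2. **Subnetwork.** On the unweighted, confidence-filtered interactome,
   connect every seed pair at shortest-path distance 1 directly and every
   pair at distance 2 through **all** single intermediaries ("imputed"
   nodes). Longer paths contribute nothing.
3. **Similarity.** Pairwise Jaccard distance between patient networks
   (node sets by default), giving a patient × patient distance matrix.
4. **Dendrogram.** UPGMA (average linkage) over that matrix; every
   internal node is a candidate cluster and receives a two-sided Fisher
   exact p-value for case/control enrichment against the rest of the
   cohort.
5. **Consensus.** For a chosen cluster, the layered union of member
   networks with per-node sample counts, origin classes
   (group-unique / shared / imputed) and degree-ranked hubs.
6. **Separation.** Between two consensus networks A and B, the
   network-medicine separation score on the interactome

   s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩) / 2,

   where ⟨d_AA⟩ averages each node's distance to the nearest *other*
   node of its own set and ⟨d_AB⟩ the distance to the nearest node of the
   opposite set. s_AB > 0 means the two modules occupy separate
   interactome neighbourhoods.

When controls vastly outnumber cases, a **balancing** workflow repeatedly
clusters the cases against a random control subsample and accumulates the
controls of each run's most control-dominated significant cluster
(largest control count, fewer than two cases); the deduplicated selection
is then compared head-to-head against the cases.

A **synthetic-cohort generator** (scale-free interactome with planted
dense modules, group-shifted Gaussian z-scores, mutation bookkeeping
tables) provides ground-truthed inputs for every stage.

## Worked example

```python
import ppiclust as pc

cfg = pc.SimulationConfig(
    n_cases=20, n_controls=60, n_background_nodes=2000,
    modules=(pc.ModuleSpec("CASEMOD", 50, "case", 3.0),
             pc.ModuleSpec("CTRLMOD", 50, "control", 3.0)),
    k_seeds=50, seed=1)
cohort = pc.simulate_cohort(cfg)
cases = sorted(p for p, g in cohort.labels.items() if g == "case")
controls = sorted(p for p, g in cohort.labels.items() if g == "control")

result = pc.final_comparison(cases, controls, cohort.expression,
                             cohort.interactome, k=50)
cc = result.case_cluster
print(f"case cluster: {cc.n_case} cases / {cc.n_control} controls, "
      f"Fisher p = {cc.fisher_p:.3g}")
planted = cohort.genes_for_group("case")
cover = len(planted & set(result.case_consensus.nodes)) / len(planted)
print(f"planted case-module genes recovered: {100*cover:.0f}%")
print(f"s_AB (group-unique nodes) = {result.separation.s_AB:.3f}")
```

prints

```
case cluster: 20 cases / 0 controls, Fisher p = 2.83e-19
planted case-module genes recovered: 100%
s_AB (group-unique nodes) = 0.406
```

The 20 simulated cases — whose expression elevates a planted 50-gene
interactome module — form a pure, highly significant cluster; its
consensus network contains every planted gene; and the positive s_AB says
the case-specific and control-specific consensus signals occupy separate
interactome neighbourhoods.

The same pipeline is available from the shell:

```sh
ppiclust --seed 1 --outdir run simulate --n-cases 20 --n-controls 60
ppiclust --seed 1 --outdir run cluster \
    --interactome run/interactome.tsv --expression run/expression.tsv \
    --labels run/labels.tsv
```

See `ppiclust --help` for the `balance`, `compare`, `separate` and
`select-k` subcommands.

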