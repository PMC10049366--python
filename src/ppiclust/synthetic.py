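"""Synthetic cohorts with planted network structure.

Generates every input the pipeline reads — a scale-free interactome with
planted dense modules, a patient x gene z-score matrix, phenotype labels
and a per-patient mutation table — together with the ground truth, so the
whole pipeline can be exercised and validated without any external data.

The generative model: a preferential-attachment background graph; each
planted module is a set of extra genes wired internally at a requested
edge density and attached to the background by a small number of bridge
edges (few bridges => the modules sit far apart in the interactome, which
is what makes a positive s_AB between recovered clusters expected).
Expression is z[i, g] ~ Normal(delta * 1[g in module(group(i))], 1): every
patient shares the standard-normal background, and genes of the module
planted for that patient's own phenotype group are shifted up by the
effect size delta, so top-k ranking by z-score recovers module genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: the seven mismatch-repair genes used for case labels in the motivating
#: breast-cancer analysis; used here as the default mutation bookkeeping set
MMR_GENES = ("MSH2", "MSH3", "MSH6", "MLH1", "PMS1", "MLH3", "PMS2")


@dataclass
class ModuleSpec:
    """One planted interactome module tied to a phenotype group."""

    module_id: str
    n_genes: int
    target_group: str            # "case" or "control"
    delta: float = 3.0           # z-score shift for the target group
    density: float = 0.3         # internal edge density (0..1]
    n_bridges: int = 2           # edges tying the module to the background


@dataclass
class SimulationConfig:
    """Study-scale defaults mirror the motivating cohort: 29 cases vs 965
    controls, k = 150 seeds, a 2,000-node interactome with one planted
    module of 50 genes per group shifted by delta = 3 z-units."""

    n_cases: int = 29
    n_controls: int = 965
    n_background_nodes: int = 2000
    attachment: int = 3          # preferential-attachment parameter m
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec("CASEMOD", 50, "case"),
        ModuleSpec("CTRLMOD", 50, "control"),
    )
    k_seeds: int = 150
    seed: int = 0

    def __post_init__(self):
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValueError("module ids must be unique")


@dataclass
class SyntheticCohort:
    interactome: nx.Graph
    expression: pd.DataFrame                  # patients x genes, z-scores
    labels: dict[str, str]                    # patient -> case|control
    module_genes: dict[str, list[str]]        # module_id -> gene list
    module_groups: dict[str, str]             # module_id -> target group
    mutations: pd.DataFrame                   # patient, gene, mut_class
    config: SimulationConfig

    def genes_for_group(self, group: str) -> set[str]:
        out: set[str] = set()
        for mid, grp in self.module_groups.items():
            if grp == group:
                out.update(self.module_genes[mid])
        return out


def simulate_interactome(
    n_nodes: int,
    modules: Sequence[ModuleSpec] = (),
    model: str = "preferential_attachment",
    attachment: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[nx.Graph, dict[str, list[str]]]:
    """Scale-free background graph with planted modules.

    Returns the graph (edges carry integer ``score`` attributes drawn
    uniformly in 400-1000, so any threshold <= 400 keeps everything) and
    the module_id -> gene list mapping. Background nodes are named G0000…,
    module genes ``<module_id>_<i>``.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    rng = rng if rng is not None else np.random.default_rng()
    if model == "preferential_attachment":
        base = nx.barabasi_albert_graph(
            n_nodes, attachment,
            seed=int(rng.integers(2**31)))
    elif model == "configuration":
        degs = rng.integers(1, 2 * attachment + 1, size=n_nodes)
        if degs.sum() % 2:
            degs[0] += 1
        base = nx.Graph(nx.configuration_model(
            degs.tolist(), seed=int(rng.integers(2**31))))
        base.remove_edges_from(nx.selfloop_edges(base))
        # keep the giant component so bridge attachment lands in it
        giant = max(nx.connected_components(base), key=len)
        base = base.subgraph(giant).copy()
    else:
        raise ValueError(f"unknown interactome model {model!r}")

    g = nx.Graph()
    background = [f"G{i:04d}" for i in sorted(base.nodes)]
    relabel = {i: background[idx] for idx, i in enumerate(sorted(base.nodes))}
    for u, v in base.edges:
        g.add_edge(relabel[u], relabel[v])

    module_genes: dict[str, list[str]] = {}
    for spec in modules:
        genes = [f"{spec.module_id}_{i:03d}" for i in range(spec.n_genes)]
        module_genes[spec.module_id] = genes
        n_possible = spec.n_genes * (spec.n_genes - 1) // 2
        n_edges = int(round(spec.density * n_possible))
        if n_edges < spec.n_genes - 1:
            raise ValueError(
                f"module {spec.module_id}: density {spec.density} gives "
                f"{n_edges} edges, fewer than the {spec.n_genes - 1} needed "
                "for a connected module")
        # random spanning tree first, then fill to the target density
        order = list(rng.permutation(spec.n_genes))
        chosen: set[frozenset] = set()
        for a, b in zip(order, order[1:]):
            chosen.add(frozenset((genes[a], genes[b])))
        pairs = [(i, j) for i in range(spec.n_genes)
                 for j in range(i + 1, spec.n_genes)]
        for idx in rng.permutation(len(pairs)):
            if len(chosen) >= n_edges:
                break
            i, j = pairs[idx]
            chosen.add(frozenset((genes[i], genes[j])))
        for e in chosen:
            a, b = sorted(e)
            g.add_edge(a, b)
        if spec.n_bridges < 1:
            raise ValueError("each module needs >= 1 bridge edge")
        anchors = rng.choice(len(background), size=spec.n_bridges,
                             replace=False)
        ends = rng.choice(spec.n_genes, size=spec.n_bridges, replace=True)
        for a_idx, m_idx in zip(anchors, ends):
            g.add_edge(background[a_idx], genes[m_idx])

    all_module_genes = [x for gs in module_genes.values() for x in gs]
    if len(set(all_module_genes)) != len(all_module_genes):
        raise ValueError("module gene sets overlap")

    for u, v in g.edges:
        g.edges[u, v]["score"] = int(rng.integers(400, 1001))
    return g, module_genes


def simulate_expression(
    net: nx.Graph,
    config: SimulationConfig,
    module_genes: Mapping[str, Sequence[str]],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Patient x gene z-score matrix with group-specific module elevation."""
    rng = rng if rng is not None else np.random.default_rng()
    patients = ([f"CASE_{i:04d}" for i in range(config.n_cases)]
                + [f"CTRL_{i:04d}" for i in range(config.n_controls)])
    labels = {p: ("case" if p.startswith("CASE_") else "control")
              for p in patients}
    genes = sorted(net.nodes)
    gene_idx = {gene: i for i, gene in enumerate(genes)}

    z = rng.standard_normal((len(patients), len(genes)))
    for spec in config.modules:
        cols = [gene_idx[gene] for gene in module_genes[spec.module_id]
                if gene in gene_idx]
        rows = [i for i, p in enumerate(patients)
                if labels[p] == spec.target_group]
        z[np.ix_(rows, cols)] += spec.delta
    expr = pd.DataFrame(z, index=patients, columns=genes)
    return expr, labels


def simulate_mutations(
    labels: Mapping[str, str],
    rng: np.random.Generator | None = None,
    genes: Sequence[str] = MMR_GENES,
    driver_rate_case: float = 0.3,
    vus_rate: float = 0.05,
) -> pd.DataFrame:
    """Per-patient mutation bookkeeping table (driver / VUS classes).

    Cases carry at least one driver mutation in one of ``genes``
    (mirroring a deficiency definition based on qualifying somatic
    mutations); VUSs are sprinkled over everyone. Purely for frequency
    bookkeeping — mutations do not feed back into expression.
    """
    rng = rng if rng is not None else np.random.default_rng()
    rows: list[tuple[str, str, str]] = []
    for patient in sorted(labels):
        if labels[patient] == "case":
            hit = genes[int(rng.integers(len(genes)))]
            rows.append((patient, hit, "driver"))
            for gene in genes:
                if gene != hit and rng.random() < driver_rate_case / len(genes):
                    rows.append((patient, gene, "driver"))
        for gene in genes:
            if rng.random() < vus_rate:
                rows.append((patient, gene, "VUS"))
    return pd.DataFrame(rows, columns=["patient", "gene", "mut_class"])


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """One-call generation of all pipeline inputs plus the ground truth.

    Deterministic in ``config.seed``: interactome, expression and mutation
    RNG streams are derived from it by fixed offsets.
    """
    net, module_genes = simulate_interactome(
        config.n_background_nodes, config.modules,
        attachment=config.attachment,
        rng=np.random.default_rng([config.seed, 0]))
    expr, labels = simulate_expression(
        net, config, module_genes, rng=np.random.default_rng([config.seed, 1]))
    muts = simulate_mutations(
        labels, rng=np.random.default_rng([config.seed, 2]))
    return SyntheticCohort(
        interactome=net, expression=expr, labels=labels,
        module_genes={m: list(v) for m, v in module_genes.items()},
        module_groups={m.module_id: m.target_group for m in config.modules},
        mutations=muts, config=config,
    )


def _round_half_away(x: float, ndigits: int = 1) -> float:
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def mutation_frequency_table(
    members: Sequence[str],
    mutations: pd.DataFrame,
    include_vus: bool = False,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene mutation frequency among a set of patients.

    frequency_pct = percent of members carrying at least one qualifying
    mutation in the gene, rounded to one decimal (half away from zero).
    VUS records qualify only with ``include_vus``.
    """
    if not len(members):
        raise ValueError("empty member set")
    member_set = set(members)
    qualifying = mutations[mutations["patient"].isin(member_set)]
    if not include_vus:
        qualifying = qualifying[qualifying["mut_class"] != "VUS"]
    gene_list = (list(genes) if genes is not None
                 else sorted(mutations["gene"].unique()))
    counts = (qualifying.drop_duplicates(["patient", "gene"])
              .groupby("gene")["patient"].count())
    rows = []
    for gene in gene_list:
        n = int(counts.get(gene, 0))
        pct = _round_half_away(100.0 * n / len(member_set))
        rows.append((gene, n, pct))
    return pd.DataFrame(rows, columns=["gene", "n_mutated", "frequency_pct"])


# ---------------------------------------------------------------------------
# Writers: the same formats the pipeline reads
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write interactome / expression / labels / mutations / truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactome": outdir / "interactome.tsv",
        "expression": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "mutations": outdir / "mutations.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["interactome"], "w") as fh:
        for u, v, d in sorted(
                (min(u, v), max(u, v), d)
                for u, v, d in cohort.interactome.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['score']}\n")
    cohort.expression.to_csv(paths["expression"], sep="\t")
    with open(paths["labels"], "w") as fh:
        for p in sorted(cohort.labels):
            fh.write(f"{p}\t{cohort.labels[p]}\n")
    cohort.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({
            "module_genes": cohort.module_genes,
            "module_groups": cohort.module_groups,
            "labels": cohort.labels,
        }, fh, indent=1, sort_keys=True)
    return paths
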