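"""Class-imbalance balancing and the final case-vs-control comparison.

When the control group dwarfs the case group, clustering the full cohort
is dominated by control-control similarity. The balancing workflow runs
the pipeline repeatedly on the cases plus a fresh random control subsample;
each run's most control-dominated significant cluster (most controls,
fewer than two cases) contributes its controls to a growing "selected"
list. After a fixed number of iterations the deduplicated selected
controls are compared head-to-head against the cases: dendrogram,
enrichment, per-group consensus networks and the s_AB separation between
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import (ClusterRecord, TreeNode, dominated_clusters,
                         enumerate_clusters, similarity_matrix, upgma)
from .consensus import ConsensusNetwork, SeparationResult, build_consensus, \
    separation_sab
from .sample_networks import SampleNetwork, build_all_networks

logger = logging.getLogger("ppiclust")

DEFAULT_N_ITERATIONS = 15
DEFAULT_ALPHA = 0.05
#: controls sampled per iteration, as a multiple of the case count
DEFAULT_CONTROL_MULTIPLE = 3


@dataclass
class PipelineResult:
    """One full clustering run: networks, tree and enrichment report."""

    networks: dict[str, SampleNetwork]
    patients: list[str]
    distance: np.ndarray
    tree: TreeNode
    clusters: list[ClusterRecord]


def run_pipeline(
    patients: Sequence[str],
    expr: pd.DataFrame,
    net: nx.Graph,
    labels: Mapping[str, str],
    k: int,
    gene_map=None,
    alpha: float = DEFAULT_ALPHA,
    jaccard_mode: str = "nodes",
    case_label: str = "case",
    networks: Mapping[str, SampleNetwork] | None = None,
) -> PipelineResult:
    """Seed selection -> networks -> Jaccard -> UPGMA -> Fisher enrichment.

    Prebuilt ``networks`` may be passed to avoid recomputation across
    balancing iterations (only the listed patients are used).
    """
    if networks is None:
        nets = build_all_networks(expr, patients, net, k, gene_map=gene_map)
    else:
        nets = {p: networks[p] for p in patients if p in networks}
    pats, D = similarity_matrix(nets, mode=jaccard_mode)
    tree = upgma(pats, D)
    clusters = enumerate_clusters(tree, labels, alpha=alpha,
                                  case_label=case_label)
    return PipelineResult(networks=dict(nets), patients=pats, distance=D,
                          tree=tree, clusters=clusters)


@dataclass
class IterationRecord:
    iteration: int
    seed: int
    sampled_controls: tuple[str, ...]
    qualifying_cluster: str | None
    newly_selected: tuple[str, ...]


@dataclass
class BalancedCohort:
    cases: tuple[str, ...]
    selected_controls: tuple[str, ...]
    iterations: list[IterationRecord]

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": [r.iteration for r in self.iterations],
            "seed": [r.seed for r in self.iterations],
            "n_sampled": [len(r.sampled_controls) for r in self.iterations],
            "cluster": [r.qualifying_cluster or "" for r in self.iterations],
            "n_newly_selected": [len(r.newly_selected) for r in self.iterations],
        })


def run_balancing(
    cases: Sequence[str],
    controls: Sequence[str],
    expr: pd.DataFrame,
    net: nx.Graph,
    k: int,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    controls_per_iter: int | None = None,
    seed: int = 0,
    gene_map=None,
    alpha: float = DEFAULT_ALPHA,
    jaccard_mode: str = "nodes",
    max_cases_in_cluster: int = 2,
) -> BalancedCohort:
    """Select a comparable control subset by repeated random subsampling.

    Each iteration draws ``controls_per_iter`` controls without replacement
    (default: three times the case count), clusters them together with all
    cases, and—among significant clusters containing fewer than
    ``max_cases_in_cluster`` cases—takes the one with the most controls
    (ties: lower p). Its controls join the selected list. Selected controls
    are deduplicated across iterations (set semantics). Fully reproducible
    from the master seed: iteration i uses an RNG stream derived from
    (seed, i).
    """
    cases = sorted(dict.fromkeys(cases))
    controls = sorted(dict.fromkeys(controls))
    overlap = set(cases) & set(controls)
    if overlap:
        raise ValueError(f"patients in both groups: {sorted(overlap)[:5]}")
    if len(controls) <= len(cases):
        raise ValueError("balancing requires more controls than cases")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if controls_per_iter is None:
        controls_per_iter = min(DEFAULT_CONTROL_MULTIPLE * len(cases),
                                len(controls))
    labels = {p: "case" for p in cases} | {p: "control" for p in controls}

    # case networks never change across iterations; build once
    case_nets = build_all_networks(expr, cases, net, k, gene_map=gene_map)
    control_nets: dict[str, SampleNetwork] = {}

    selected: dict[str, None] = {}   # insertion-ordered set
    records: list[IterationRecord] = []
    for it in range(n_iterations):
        rng = np.random.default_rng([seed, it])
        sample = sorted(str(p) for p in rng.choice(
            controls, size=controls_per_iter, replace=False))
        for pid in sample:
            if pid not in control_nets:
                control_nets.update(build_all_networks(
                    expr, [pid], net, k, gene_map=gene_map))
        nets = {**case_nets, **{p: control_nets[p] for p in sample}}
        result = run_pipeline(
            list(nets), expr, net, labels, k, alpha=alpha,
            jaccard_mode=jaccard_mode, networks=nets,
        )
        qualifying = [
            r for r in result.clusters
            if r.significant and r.n_case < max_cases_in_cluster
        ]
        qualifying.sort(key=lambda r: (-r.n_control, r.fisher_p,
                                       sorted(r.members)))
        if qualifying:
            best = qualifying[0]
            new = tuple(p for p in sorted(best.members)
                        if labels[p] == "control" and p not in selected)
            for p in new:
                selected[p] = None
            records.append(IterationRecord(
                iteration=it, seed=seed,
                sampled_controls=tuple(sample),
                qualifying_cluster=best.node, newly_selected=new))
            logger.info("iteration %d: cluster %s (%d controls, %d cases, "
                        "p=%.3g), %d newly selected", it, best.node,
                        best.n_control, best.n_case, best.fisher_p, len(new))
        else:
            records.append(IterationRecord(
                iteration=it, seed=seed,
                sampled_controls=tuple(sample),
                qualifying_cluster=None, newly_selected=()))
            logger.info("iteration %d: no qualifying cluster", it)

    assert not (set(selected) & set(cases))
    return BalancedCohort(cases=tuple(cases),
                          selected_controls=tuple(sorted(selected)),
                          iterations=records)


@dataclass
class ComparisonResult:
    pipeline: PipelineResult
    case_cluster: ClusterRecord | None
    control_cluster: ClusterRecord | None
    case_consensus: ConsensusNetwork | None
    control_consensus: ConsensusNetwork | None
    separation: SeparationResult | None
    skipped: str | None = None


def final_comparison(
    cases: Sequence[str],
    selected_controls: Sequence[str],
    expr: pd.DataFrame,
    net: nx.Graph,
    k: int,
    gene_map=None,
    alpha: float = DEFAULT_ALPHA,
    jaccard_mode: str = "nodes",
    domination_fraction: float = 0.9,
    consensus_min_fraction: float = 0.0,
    separation_nodes: str = "unique",
) -> ComparisonResult:
    """Head-to-head comparison of the cases and the selected controls.

    Clusters the combined cohort; picks the most case-dominated and the
    most control-dominated significant clusters (most members of the
    group, ties by lower p); builds their consensus networks with origin
    labels, and scores the s_AB separation between them.

    ``separation_nodes`` chooses which consensus nodes enter the s_AB
    comparison: ``"unique"`` (default) uses each network's group-unique
    nodes, so the score measures how far apart the group-specific signal
    sits in the interactome; ``"full"`` uses the complete node sets — note
    that any node shared by both consensuses then contributes a zero
    cross-distance, which drives s_AB negative whenever the consensuses
    overlap at all. If either side lacks a qualifying cluster the
    consensus and separation steps are skipped with an explicit report.
    """
    if separation_nodes not in ("unique", "full"):
        raise ValueError("separation_nodes must be 'unique' or 'full'")
    cases = sorted(dict.fromkeys(cases))
    ctrls = sorted(dict.fromkeys(selected_controls))
    if len(cases) < 2 or len(ctrls) < 2:
        raise ValueError("both groups need at least 2 patients")
    labels = {p: "case" for p in cases} | {p: "control" for p in ctrls}
    result = run_pipeline(cases + ctrls, expr, net, labels, k,
                          gene_map=gene_map, alpha=alpha,
                          jaccard_mode=jaccard_mode)

    case_dom = dominated_clusters(result.clusters, "case",
                                  min_fraction=domination_fraction)
    ctrl_dom = dominated_clusters(result.clusters, "control",
                                  min_fraction=domination_fraction)
    case_cluster = case_dom[0] if case_dom else None
    ctrl_cluster = ctrl_dom[0] if ctrl_dom else None

    skipped = None
    case_cons = ctrl_cons = separation = None
    if case_cluster is None or ctrl_cluster is None:
        missing = []
        if case_cluster is None:
            missing.append("case")
        if ctrl_cluster is None:
            missing.append("control")
        skipped = ("no significant dominated cluster for group(s): "
                   + ", ".join(missing)
                   + "; consensus and separation skipped")
        logger.warning(skipped)
    else:
        in_both = lambda r: [p for p in sorted(r.members)]
        case_members = in_both(case_cluster)
        ctrl_members = in_both(ctrl_cluster)
        case_cons = build_consensus(
            case_members, result.networks, opposing_members=ctrl_members,
            min_fraction=consensus_min_fraction,
            cluster_id=f"case_{case_cluster.node}", group="case")
        ctrl_cons = build_consensus(
            ctrl_members, result.networks, opposing_members=case_members,
            min_fraction=consensus_min_fraction,
            cluster_id=f"control_{ctrl_cluster.node}", group="control")
        if separation_nodes == "unique":
            set_a = {n for n in case_cons.nodes
                     if case_cons.origin[n] == "group_unique"}
            set_b = {n for n in ctrl_cons.nodes
                     if ctrl_cons.origin[n] == "group_unique"}
        else:
            set_a, set_b = set(case_cons.nodes), set(ctrl_cons.nodes)
        if len(set_a) < 2 or len(set_b) < 2:
            # very large clusters can saturate the interactome under a
            # pure-union consensus, leaving no group-unique nodes
            skipped = (
                f"separation skipped: node sets too small "
                f"(|A|={len(set_a)}, |B|={len(set_b)}); consider "
                "consensus_min_fraction > 0 or separation_nodes='full'")
            logger.warning(skipped)
        else:
            separation = separation_sab(set_a, set_b, net)
            logger.info("s_AB between consensus networks: %.3f",
                        separation.s_AB)

    return ComparisonResult(
        pipeline=result,
        case_cluster=case_cluster,
        control_cluster=ctrl_cluster,
        case_consensus=case_cons,
        control_consensus=ctrl_cons,
        separation=separation,
        skipped=skipped,
    )
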