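"""Consensus networks of patient clusters and topological separation.

The consensus network of a cluster is the layered union of its members'
subnetworks, each node and edge annotated with the number of member
networks containing it. Nodes are classified by origin relative to the
opposing group's consensus (group-unique / shared / imputed), hubs are
ranked by degree, and the separation between two node sets A and B on the
interactome is quantified by the network-medicine separation score

    s_AB = <d_AB> - (<d_AA> + <d_BB>) / 2

where <d_AA> averages, over nodes of A, the shortest-path distance to the
nearest *other* node of A, and <d_AB> averages over all nodes of A and B
the distance to the nearest node of the opposite set (0 if the node is in
both). Positive s_AB means the two modules occupy separate interactome
neighbourhoods; negative means they overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .sample_networks import SampleNetwork

logger = logging.getLogger("ppiclust")


@dataclass
class ConsensusNetwork:
    """Layered union network of one patient cluster."""

    cluster_id: str
    members: tuple[str, ...]
    node_counts: dict[str, int]            # node -> number of member networks
    edge_counts: dict[frozenset, int]      # edge -> number of member networks
    origin: dict[str, str]                 # node -> origin class
    group: str = ""

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.node_counts)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edge_counts if node in e)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for n, c in self.node_counts.items():
            g.add_node(n, sample_count=c, origin=self.origin[n])
        for e, c in self.edge_counts.items():
            a, b = sorted(e)
            g.add_edge(a, b, sample_count=c)
        return g


def _layered_union(
    members: Sequence[str], networks: Mapping[str, SampleNetwork]
) -> tuple[dict[str, int], dict[frozenset, int], set[str]]:
    node_counts: dict[str, int] = {}
    edge_counts: dict[frozenset, int] = {}
    seed_anywhere: set[str] = set()
    for pid in members:
        sn = networks[pid]
        for n in sn.nodes:
            node_counts[n] = node_counts.get(n, 0) + 1
        for e in sn.edges:
            edge_counts[e] = edge_counts.get(e, 0) + 1
        seed_anywhere |= sn.seed_nodes
    return node_counts, edge_counts, seed_anywhere


def build_consensus(
    cluster_members: Sequence[str],
    networks: Mapping[str, SampleNetwork],
    opposing_members: Sequence[str] = (),
    min_fraction: float = 0.0,
    cluster_id: str = "",
    group: str = "",
) -> ConsensusNetwork:
    """Union the member networks of one cluster into a consensus network.

    Nodes appearing in fewer than ``ceil(min_fraction * n_members)`` member
    networks are pruned (default 0: pure union; edges incident to pruned
    nodes go too). Origin classes compare against the union of the
    ``opposing_members`` networks: a node only here is group-unique, a node
    in both consensuses is shared, and a node that entered *every* member
    network purely as a length-2 intermediary is labelled imputed (seed
    status in any member wins over imputed status).
    """
    if not cluster_members:
        raise ValueError("empty cluster member set")
    missing = [p for p in cluster_members if p not in networks]
    if missing:
        raise ValueError(f"members without built networks: {missing[:5]}")

    node_counts, edge_counts, seed_anywhere = _layered_union(
        cluster_members, networks)

    if min_fraction > 0:
        cutoff = int(np.ceil(min_fraction * len(cluster_members)))
        node_counts = {n: c for n, c in node_counts.items() if c >= cutoff}
        edge_counts = {e: c for e, c in edge_counts.items()
                       if all(n in node_counts for n in e)}

    opposing_nodes: set[str] = set()
    for pid in opposing_members:
        if pid in networks:
            opposing_nodes |= networks[pid].nodes

    origin: dict[str, str] = {}
    for n in node_counts:
        if n not in seed_anywhere:
            origin[n] = "imputed"
        elif n in opposing_nodes:
            origin[n] = "shared"
        else:
            origin[n] = "group_unique"

    return ConsensusNetwork(
        cluster_id=cluster_id,
        members=tuple(cluster_members),
        node_counts=node_counts,
        edge_counts=edge_counts,
        origin=origin,
        group=group,
    )


def rank_hubs(consensus: ConsensusNetwork, top_n: int = 10) -> pd.DataFrame:
    """Top-degree nodes of a consensus network.

    Sorted by degree (desc), then sample_count (desc), then node id. The
    ``exclusive`` flag marks group-unique nodes.
    """
    if not consensus.node_counts:
        raise ValueError("empty consensus network")
    deg: dict[str, int] = {n: 0 for n in consensus.node_counts}
    for e in consensus.edge_counts:
        for n in e:
            deg[n] += 1
    rows = sorted(
        deg,
        key=lambda n: (-deg[n], -consensus.node_counts[n], n),
    )[:top_n]
    return pd.DataFrame({
        "node": rows,
        "degree": [deg[n] for n in rows],
        "sample_count": [consensus.node_counts[n] for n in rows],
        "origin": [consensus.origin[n] for n in rows],
        "exclusive": [consensus.origin[n] == "group_unique" for n in rows],
    })


# ---------------------------------------------------------------------------
# Separation score
# ---------------------------------------------------------------------------

@dataclass
class SeparationResult:
    d_AA: float
    d_BB: float
    d_AB: float
    s_AB: float
    n_A: int
    n_B: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _nearest_distances(
    net: nx.Graph, sources: Iterable[str], targets: set[str],
    exclude_self: bool,
) -> tuple[list[float], int]:
    """For each source, hop distance to the nearest target (optionally
    excluding the source itself). Returns (distances, n_unreachable)."""
    dists: list[float] = []
    n_unreachable = 0
    for s in sources:
        if not exclude_self and s in targets:
            dists.append(0.0)
            continue
        best = None
        # bounded BFS: stop as soon as a frontier contains a target
        seen = {s}
        frontier = [s]
        depth = 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in net.adj[u]:
                    if v in seen:
                        continue
                    seen.add(v)
                    if v in targets and (not exclude_self or v != s):
                        best = depth
                    nxt.append(v)
            if best is not None:
                break
            frontier = nxt
        if best is None:
            n_unreachable += 1
        else:
            dists.append(float(best))
    return dists, n_unreachable


def separation_sab(
    set_a: Iterable[str], set_b: Iterable[str], net: nx.Graph
) -> SeparationResult:
    """Topological separation s_AB of two node sets on the interactome.

    Distances are unweighted shortest paths on the full filtered
    interactome. Nodes absent from the interactome are dropped up front;
    nodes with no reachable candidate target are excluded from the relevant
    mean and counted in ``n_excluded``.
    """
    A = {n for n in set_a if n in net}
    B = {n for n in set_b if n in net}
    if not A or not B:
        raise ValueError("a node set is empty after mapping to the interactome")
    if len(A) < 2 or len(B) < 2:
        raise ValueError(
            "within-set mean distance undefined for a singleton set; "
            "provide at least 2 mapped nodes per set"
        )

    d_aa, ex1 = _nearest_distances(net, sorted(A), A, exclude_self=True)
    d_bb, ex2 = _nearest_distances(net, sorted(B), B, exclude_self=True)
    d_ab_a, ex3 = _nearest_distances(net, sorted(A), B, exclude_self=False)
    d_ab_b, ex4 = _nearest_distances(net, sorted(B), A, exclude_self=False)
    if not d_aa or not d_bb or not (d_ab_a or d_ab_b):
        raise ValueError("all distances unreachable; sets lie in disconnected "
                         "components of the interactome")

    mean_aa = float(np.mean(d_aa))
    mean_bb = float(np.mean(d_bb))
    mean_ab = float(np.mean(d_ab_a + d_ab_b))
    s = mean_ab - (mean_aa + mean_bb) / 2.0
    return SeparationResult(
        d_AA=mean_aa, d_BB=mean_bb, d_AB=mean_ab, s_AB=s,
        n_A=len(A), n_B=len(B), n_excluded=ex1 + ex2 + ex3 + ex4,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_consensus(consensus: ConsensusNetwork, outdir: str | Path) -> None:
    """Edge-list TSV + node attribute TSV for a consensus network."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = consensus.cluster_id or "consensus"
    with open(outdir / f"{base}.edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tsample_count\n")
        for e in sorted(sorted(e) for e in consensus.edge_counts):
            c = consensus.edge_counts[frozenset(e)]
            fh.write(f"{e[0]}\t{e[1]}\t{c}\n")
    deg: dict[str, int] = {n: 0 for n in consensus.node_counts}
    for e in consensus.edge_counts:
        for n in e:
            deg[n] += 1
    with open(outdir / f"{base}.nodes.tsv", "w") as fh:
        fh.write("node\tsample_count\torigin\tdegree\n")
        for n in sorted(consensus.node_counts):
            fh.write(f"{n}\t{consensus.node_counts[n]}\t"
                     f"{consensus.origin[n]}\t{deg[n]}\n")
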