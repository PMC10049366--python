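"""Per-patient seed selection and PPI subnetwork construction.

Each patient contributes their top-k most upregulated genes (by expression
z-score) as seeds. The patient's subnetwork is the union, over all seed
pairs, of shortest paths of length at most ``max_path_len`` hops in the
unweighted interactome: directly interacting seed pairs contribute their
edge, pairs at distance exactly 2 contribute every single-intermediary
("imputed") node lying on a shortest path between them. Unit-weight
Dijkstra and BFS coincide, so plain neighbourhood intersection suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("ppiclust")


@dataclass
class SampleNetwork:
    """One patient's PPI subnetwork.

    ``seed_nodes`` and ``imputed_nodes`` are disjoint; every edge joins a
    seed to a seed or a seed to an imputed intermediary. Seeds with no
    qualifying connection remain in ``seed_nodes`` as isolated nodes and
    are listed in ``isolated_seeds``.
    """

    patient_id: str
    seed_nodes: frozenset[str]
    imputed_nodes: frozenset[str]
    edges: frozenset[frozenset[str]]
    k_seeds: int
    isolated_seeds: frozenset[str] = frozenset()

    @property
    def nodes(self) -> frozenset[str]:
        return self.seed_nodes | self.imputed_nodes

    def element_set(self, mode: str = "nodes") -> frozenset:
        """Element universe used for Jaccard similarity.

        ``nodes`` (default), ``edges``, or ``nodes+edges`` (disjoint union).
        """
        if mode == "nodes":
            return self.nodes
        if mode == "edges":
            return self.edges
        if mode == "nodes+edges":
            return frozenset(self.nodes) | self.edges
        raise ValueError(f"unknown jaccard mode {mode!r}")


def load_expression_matrix(
    path: str | Path, patients_as_rows: bool = True, sep: str = "\t"
) -> pd.DataFrame:
    """Read a delimited z-score matrix into a patients x genes DataFrame."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not patients_as_rows:
        df = df.T
    validate_expression_matrix(df)
    return df


def validate_expression_matrix(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        raise ValueError("duplicate patient ids in expression matrix")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate gene symbols in expression matrix")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite entries")


def load_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (patient_id, group) into a dict."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["patient", "group"],
                     comment="#", dtype=str)
    return dict(zip(df["patient"], df["group"]))


def select_seed_genes(
    expr: pd.DataFrame,
    patient_id: str,
    k: int,
    positive_only: bool = False,
) -> list[str]:
    """Return the k genes with the largest z-score for one patient.

    Ties are broken lexicographically by gene symbol so that ranking is
    deterministic across platforms. With ``positive_only`` genes with
    z <= 0 never qualify, which can return fewer than k genes.
    """
    if patient_id not in expr.index:
        raise KeyError(f"unknown patient {patient_id!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    row = expr.loc[patient_id]
    if k > len(row):
        logger.warning("k=%d exceeds gene count %d; returning all genes ranked",
                       k, len(row))
        k = len(row)
    # sort by (-z, symbol): stable, deterministic under ties
    order = sorted(zip(-row.to_numpy(dtype=float), row.index.astype(str)))
    ranked = [g for negz, g in order if not (positive_only and negz >= 0)]
    return ranked[:k]


def build_sample_network(
    seeds: Sequence[str],
    net: nx.Graph,
    max_path_len: int = 2,
    patient_id: str = "",
    keep_isolated_seeds: bool = True,
) -> SampleNetwork:
    """Expand a seed set into a patient subnetwork on the interactome.

    For every unordered seed pair at distance 1 the direct edge is added;
    at distance exactly 2 (and ``max_path_len`` >= 2) ALL common neighbours
    are added as imputed nodes together with both path edges. Pairs farther
    apart contribute nothing. Seeds absent from the interactome are ignored
    here (map them first); an empty effective seed set is an error.
    """
    if max_path_len not in (1, 2):
        raise ValueError("max_path_len must be 1 or 2")
    seed_list = [s for s in dict.fromkeys(seeds) if s in net]
    if not seed_list:
        raise ValueError(f"empty seed set for patient {patient_id!r}")
    seed_set = set(seed_list)

    adj: dict[str, set[str]] = {s: set(net.adj[s]) for s in seed_list}
    edges: set[frozenset[str]] = set()
    imputed: set[str] = set()
    connected: set[str] = set()

    for u, v in combinations(seed_list, 2):
        if v in adj[u]:
            edges.add(frozenset((u, v)))
            connected.update((u, v))
        elif max_path_len >= 2:
            common = adj[u] & adj[v]
            if common:
                for w in common:
                    if w not in seed_set:
                        imputed.add(w)
                    # w may be a seed: then u-w and w-v are distance-1 seed
                    # pairs handled by their own iteration; still record the
                    # path edges (idempotent).
                    edges.add(frozenset((u, w)))
                    edges.add(frozenset((w, v)))
                connected.update((u, v))
    connected.update(w for e in edges for w in e)
    isolated = seed_set - connected
    if not keep_isolated_seeds:
        seed_set -= isolated
        isolated = set()

    return SampleNetwork(
        patient_id=patient_id,
        seed_nodes=frozenset(seed_set),
        imputed_nodes=frozenset(imputed),
        edges=frozenset(edges),
        k_seeds=len(seed_list),
        isolated_seeds=frozenset(isolated),
    )


def build_all_networks(
    expr: pd.DataFrame,
    patients: Iterable[str],
    net: nx.Graph,
    k: int,
    gene_map: Mapping[str, str] | None = None,
    max_path_len: int = 2,
    positive_only: bool = False,
    keep_isolated_seeds: bool = True,
) -> dict[str, SampleNetwork]:
    """Seed selection + network construction for a set of patients.

    Patients whose seeds all fail to map are excluded with a warning.
    """
    from .interactome import map_seed_genes

    networks: dict[str, SampleNetwork] = {}
    for pid in patients:
        genes = select_seed_genes(expr, pid, k, positive_only=positive_only)
        mapped, _dropped = map_seed_genes(genes, gene_map, net)
        if not mapped:
            logger.warning("patient %s: no seed maps to the interactome; "
                           "sample excluded", pid)
            continue
        networks[pid] = build_sample_network(
            mapped, net, max_path_len=max_path_len, patient_id=pid,
            keep_isolated_seeds=keep_isolated_seeds,
        )
    return networks


def write_sample_network(sn: SampleNetwork, outdir: str | Path) -> None:
    """Export one patient network: edge-list TSV + node-role sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{sn.patient_id}.edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\n")
        for e in sorted(sorted(e) for e in sn.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
    with open(outdir / f"{sn.patient_id}.nodes.tsv", "w") as fh:
        fh.write("node_id\trole\n")
        for n in sorted(sn.seed_nodes):
            fh.write(f"{n}\tseed\n")
        for n in sorted(sn.imputed_nodes):
            fh.write(f"{n}\timputed\n")
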