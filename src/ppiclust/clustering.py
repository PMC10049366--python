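"""Network similarity, UPGMA patient dendrograms and cluster enrichment.

Pairwise Jaccard distances between patient subnetworks feed an
average-linkage (UPGMA) agglomeration. Every internal node of the
resulting ultrametric tree is a candidate patient cluster; its case/control
composition is tested against the rest of the cohort with a two-sided
Fisher exact test. Dendrograms built at different seed counts k are
compared by the cophenetic correlation coefficient.

UPGMA is implemented here rather than delegated to scipy so that merge
ties resolve by the lexicographically smallest member patient id — a
platform-independent determinism guarantee scipy's linkage does not make.
scipy.cluster.hierarchy serves as the independent cross-check in the test
suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sample_networks import SampleNetwork

logger = logging.getLogger("ppiclust")


# ---------------------------------------------------------------------------
# Jaccard similarity
# ---------------------------------------------------------------------------

def jaccard_distance(
    net_a: SampleNetwork, net_b: SampleNetwork, mode: str = "nodes"
) -> float:
    """Jaccard distance 1 - |X_a ∩ X_b| / |X_a ∪ X_b| between two networks.

    ``mode`` selects the element universe: node sets (default), edge sets,
    or their disjoint union.
    """
    xa, xb = net_a.element_set(mode), net_b.element_set(mode)
    union = xa | xb
    if not union:
        raise ValueError("Jaccard distance undefined: both element sets empty")
    return 1.0 - len(xa & xb) / len(union)


def similarity_matrix(
    networks: Mapping[str, SampleNetwork], mode: str = "nodes"
) -> tuple[list[str], np.ndarray]:
    """Symmetric patient x patient Jaccard distance matrix.

    Patients are ordered lexicographically for reproducibility.
    """
    patients = sorted(networks)
    sets = [networks[p].element_set(mode) for p in patients]
    sizes = np.array([len(s) for s in sets])
    n = len(patients)
    D = np.zeros((n, n))
    for i in range(n):
        si = sets[i]
        for j in range(i + 1, n):
            inter = len(si & sets[j])
            union = sizes[i] + sizes[j] - inter
            if union == 0:
                raise ValueError("Jaccard distance undefined: empty networks")
            D[i, j] = D[j, i] = 1.0 - inter / union
    return patients, D


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a patient dendrogram (leaf or binary internal node).

    ``height`` is half the UPGMA merge distance (d/2 convention), so the
    cophenetic distance between two leaves is ``2 * height`` of their
    lowest common ancestor. Enrichment fields are filled in by
    :func:`enumerate_clusters`.
    """

    members: frozenset[str]
    height: float = 0.0
    children: tuple["TreeNode", "TreeNode"] | None = None
    name: str | None = None          # leaf: patient id; internal: node id
    n_case: int | None = None
    n_control: int | None = None
    fisher_p: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def walk(self) -> Iterable["TreeNode"]:
        """Depth-first traversal (post-order)."""
        if self.children is not None:
            for c in self.children:
                yield from c.walk()
        yield self

    def internal_nodes(self) -> list["TreeNode"]:
        return [n for n in self.walk() if not n.is_leaf]

    @property
    def leaves(self) -> list[str]:
        return sorted(self.members)


def upgma(patients: Sequence[str], D: np.ndarray) -> TreeNode:
    """Average-linkage agglomeration of a symmetric distance matrix.

    At every step the pair of clusters with minimal average inter-cluster
    distance is merged; exact ties are broken by the lexicographically
    smallest combined member set. Merge heights are d/2.
    """
    D = np.asarray(D, dtype=float)
    n = len(patients)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 patients")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match patient list")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(D < 0) or np.any(D > 1 + 1e-12):
        raise ValueError("distances must lie in [0, 1]")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    if len(set(patients)) != n:
        raise ValueError("duplicate patient ids")

    work = D.copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))
    nodes: list[TreeNode] = [
        TreeNode(members=frozenset((p,)), name=str(p)) for p in patients
    ]
    sizes = np.ones(n)
    sortkeys = [tuple(nd.leaves) for nd in nodes]
    next_id = 0

    while len(active) > 1:
        sub = work[np.ix_(active, active)]
        m = sub.min()
        ties = np.argwhere(np.isclose(sub, m, rtol=0, atol=1e-12))
        best = None
        for ai, aj in ties:
            if ai >= aj:
                continue
            i, j = active[ai], active[aj]
            key = tuple(sorted(sortkeys[i] + sortkeys[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        merged = TreeNode(
            members=nodes[i].members | nodes[j].members,
            height=work[i, j] / 2.0,
            children=(nodes[i], nodes[j]),
            name=f"N{next_id}",
        )
        next_id += 1
        # Lance-Williams average update into slot i; retire slot j
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * work[i, :] + nj * work[j, :]) / (ni + nj)
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        work[j, :] = np.inf
        work[:, j] = np.inf
        nodes[i] = merged
        sizes[i] = ni + nj
        sortkeys[i] = tuple(merged.leaves)
        active.remove(j)

    root = nodes[active[0]]
    # number internal nodes deterministically, root first, by traversal
    for idx, node in enumerate(
        sorted(root.internal_nodes(), key=lambda nd: (-len(nd.members), nd.leaves))
    ):
        node.name = f"N{idx}"
    return root


def cophenetic_matrix(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Pairwise cophenetic distances (merge distance of the LCA)."""
    leaves = tree.leaves
    index = {p: i for i, p in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for node in tree.walk():
        if node.is_leaf:
            continue
        left, right = node.children
        d = 2.0 * node.height
        li = [index[p] for p in left.members]
        ri = [index[p] for p in right.members]
        C[np.ix_(li, ri)] = d
        C[np.ix_(ri, li)] = d
    return leaves, C


def cophenetic_correlation(tree_a: TreeNode, tree_b: TreeNode) -> float:
    """Pearson correlation of the two trees' pairwise cophenetic distances.

    Both trees must be over exactly the same patients.
    """
    la, Ca = cophenetic_matrix(tree_a)
    lb, Cb = cophenetic_matrix(tree_b)
    if la != lb:
        raise ValueError("dendrograms have different leaf sets")
    iu = np.triu_indices(len(la), k=1)
    va, vb = Ca[iu], Cb[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        # a perfectly flat tree: correlation is defined as 1 against itself
        return 1.0 if np.allclose(va, vb) else 0.0
    return float(np.corrcoef(va, vb)[0, 1])


# ---------------------------------------------------------------------------
# Cluster enrichment
# ---------------------------------------------------------------------------

def fisher_p_two_sided(n11: int, n12: int, n21: int, n22: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[n11, n12], [n21, n22]]."""
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]],
                              alternative="two-sided")
    return float(p)


@dataclass
class ClusterRecord:
    node: str
    members: frozenset[str]
    n_case: int
    n_control: int
    fisher_p: float
    significant: bool

    @property
    def size(self) -> int:
        return self.n_case + self.n_control

    def case_fraction(self) -> float:
        return self.n_case / self.size


def enumerate_clusters(
    tree: TreeNode,
    labels: Mapping[str, str],
    alpha: float = 0.05,
    case_label: str = "case",
    bh_correct: bool = False,
) -> list[ClusterRecord]:
    """Fisher-exact enrichment of every internal node against the cohort.

    For each internal node the 2x2 table
    [in-cluster case, in-cluster control; out case, out control] over all
    patients in the tree gets a two-sided Fisher exact p-value; records are
    flagged at ``alpha`` (optionally Benjamini-Hochberg adjusted).
    """
    leaves = tree.leaves
    missing = [p for p in leaves if p not in labels]
    if missing:
        raise ValueError(f"unlabeled patients: {missing[:5]}")
    total_case = sum(1 for p in leaves if labels[p] == case_label)
    total = len(leaves)

    records: list[ClusterRecord] = []
    for node in tree.internal_nodes():
        in_case = sum(1 for p in node.members if labels[p] == case_label)
        in_ctrl = len(node.members) - in_case
        out_case = total_case - in_case
        out_ctrl = (total - total_case) - in_ctrl
        p = fisher_p_two_sided(in_case, in_ctrl, out_case, out_ctrl)
        node.n_case, node.n_control, node.fisher_p = in_case, in_ctrl, float(p)
        records.append(ClusterRecord(
            node=node.name, members=node.members, n_case=in_case,
            n_control=in_ctrl, fisher_p=float(p), significant=p < alpha,
        ))

    if bh_correct:
        order = np.argsort([r.fisher_p for r in records])
        m = len(records)
        thresh = 0.0
        adj_sig = [False] * m
        # step-up: largest i with p_(i) <= i/m * alpha
        cutoff_rank = -1
        for rank, idx in enumerate(order, start=1):
            if records[idx].fisher_p <= rank / m * alpha:
                cutoff_rank = rank
        for rank, idx in enumerate(order, start=1):
            adj_sig[idx] = rank <= cutoff_rank
        for r, sig in zip(records, adj_sig):
            r.significant = sig

    records.sort(key=lambda r: (r.fisher_p, -r.size, sorted(r.members)))
    return records


def dominated_clusters(
    records: Sequence[ClusterRecord],
    group: str,
    min_fraction: float = 0.9,
) -> list[ClusterRecord]:
    """Significant clusters dominated by one group.

    ``group`` is "case" or "control"; domination means significance plus a
    member fraction of that group at or above ``min_fraction``. Sorted by
    (descending group count, ascending p).
    """
    def frac(r: ClusterRecord) -> float:
        return r.case_fraction() if group == "case" else 1 - r.case_fraction()

    def count(r: ClusterRecord) -> int:
        return r.n_case if group == "case" else r.n_control

    out = [r for r in records if r.significant and frac(r) >= min_fraction]
    out.sort(key=lambda r: (-count(r), r.fisher_p, sorted(r.members)))
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths and "n_case|n_control|p" labels."""

    def label(node: TreeNode) -> str:
        if node.fisher_p is None:
            return node.name or ""
        return f"{node.n_case}|{node.n_control}|{node.fisher_p:.3g}"

    def rec(node: TreeNode, parent_height: float) -> str:
        blen = parent_height - node.height
        if node.is_leaf:
            return f"{node.name}:{blen:.6g}"
        inner = ",".join(rec(c, node.height) for c in node.children)
        return f"({inner}){label(node)}:{blen:.6g}"

    left, right = tree.children
    inner = ",".join(rec(c, tree.height) for c in (left, right))
    return f"({inner}){label(tree)};"


def cluster_report_frame(records: Sequence[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "node": [r.node for r in records],
        "n_case": [r.n_case for r in records],
        "n_control": [r.n_control for r in records],
        "fisher_p": [r.fisher_p for r in records],
        "significant": [r.significant for r in records],
        "members": [";".join(sorted(r.members)) for r in records],
    })


def write_similarity_matrix(patients: Sequence[str], D: np.ndarray,
                            path) -> None:
    pd.DataFrame(D, index=patients, columns=patients).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Seed-count selection
# ---------------------------------------------------------------------------

def select_seed_count(
    expr: pd.DataFrame,
    patients: Sequence[str],
    candidate_ks: Sequence[int],
    net,
    gene_map=None,
    mode: str = "nodes",
) -> tuple[int, pd.DataFrame]:
    """Compare dendrograms across candidate seed counts k.

    Runs seed selection, network construction, Jaccard similarity and UPGMA
    at every k on the same patient set, then builds the k x k table of
    pairwise cophenetic correlations. The chosen k maximises the mean
    correlation with the other candidates (a stability criterion); ties go
    to the smaller k. The full table is returned so the choice can be
    overridden.
    """
    from .sample_networks import build_all_networks

    if len(candidate_ks) < 2:
        raise ValueError("need at least 2 candidate k values")
    n_genes = expr.shape[1]
    ks = []
    for k in candidate_ks:
        if k > n_genes:
            logger.warning("candidate k=%d exceeds gene count %d; dropped",
                           k, n_genes)
        else:
            ks.append(k)

    trees: dict[int, TreeNode] = {}
    for k in ks:
        networks = build_all_networks(expr, patients, net, k, gene_map=gene_map)
        pats, D = similarity_matrix(networks, mode=mode)
        trees[k] = upgma(pats, D)

    table = pd.DataFrame(np.eye(len(ks)), index=ks, columns=ks)
    for a in range(len(ks)):
        for b in range(a + 1, len(ks)):
            c = cophenetic_correlation(trees[ks[a]], trees[ks[b]])
            table.iloc[a, b] = table.iloc[b, a] = c

    means = {k: (table.loc[k].sum() - 1.0) / (len(ks) - 1) for k in ks}
    chosen = min(ks, key=lambda k: (-means[k], k))
    logger.info("seed-count selection: chose k=%d (mean cophenetic corr %.3f)",
                chosen, means[chosen])
    return chosen, table
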