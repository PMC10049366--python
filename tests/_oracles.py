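"""Independent brute-force oracles used to validate the implementation.

Everything here recomputes results from first principles (exhaustive BFS
path enumeration, hypergeometric tail sums, direct LCA scans) without
touching the code paths under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import networkx as nx


def bfs_network_oracle(seeds, g: nx.Graph):
    """Exhaustive all-pairs shortest-path enumeration at distance <= 2.

    Returns (seed_nodes, imputed_nodes, edges) exactly as the sample
    network construction should: direct edges for distance-1 seed pairs,
    every intermediary on every shortest length-2 path for distance-2
    pairs.
    """
    seeds = [s for s in dict.fromkeys(seeds) if s in g]
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
    edges: set[frozenset] = set()
    imputed: set = set()
    for u, v in combinations(seeds, 2):
        d = dist.get(u, {}).get(v)
        if d == 1:
            edges.add(frozenset((u, v)))
        elif d == 2:
            for w in g.nodes:
                if dist[u].get(w) == 1 and dist[v].get(w) == 1:
                    if w not in seeds:
                        imputed.add(w)
                    edges.add(frozenset((u, w)))
                    edges.add(frozenset((w, v)))
    return set(seeds), imputed, edges


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Table [[a, b], [c, d]]; sums the probabilities of all tables with the
    same margins whose probability does not exceed the observed one.
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, col1)

    def prob(x: int) -> float:
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > n - row1:
            return 0.0
        return comb(row1, x) * comb(n - row1, col1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def sab_oracle(set_a, set_b, g: nx.Graph):
    """Separation score from full BFS distance tables.

    Returns (d_AA, d_BB, d_AB, s_AB) with unreachable nodes excluded from
    the relevant mean.
    """
    A = sorted(n for n in set_a if n in g)
    B = sorted(n for n in set_b if n in g)
    dist = dict(nx.all_pairs_shortest_path_length(g))

    def nearest(src, targets, exclude_self):
        cand = [dist[src][t] for t in targets
                if t in dist[src] and (not exclude_self or t != src)]
        return min(cand) if cand else None

    def collect(sources, targets, exclude_self):
        out = []
        for s in sources:
            if not exclude_self and s in targets:
                out.append(0)
                continue
            d = nearest(s, targets, exclude_self)
            if d is not None:
                out.append(d)
        return out

    d_aa = collect(A, set(A), True)
    d_bb = collect(B, set(B), True)
    d_ab = collect(A, set(B), False) + collect(B, set(A), False)
    mean = lambda xs: sum(xs) / len(xs)
    s = mean(d_ab) - (mean(d_aa) + mean(d_bb)) / 2
    return mean(d_aa), mean(d_bb), mean(d_ab), s


def lca_cophenetic_oracle(tree, p, q) -> float:
    """Cophenetic distance of two leaves by direct root-to-LCA descent."""
    node = tree
    while True:
        child = next((c for c in node.children
                      if p in c.members and q in c.members), None)
        if child is None:
            return 2.0 * node.height
        node = child
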