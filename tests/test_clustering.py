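from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

import ppiclust as pc
from _oracles import fisher_two_sided_oracle, lca_cophenetic_oracle
from conftest import make_network


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------

class TestJaccard:
    def test_identity_is_zero(self):
        a = make_network("a", {"A", "B"})
        assert pc.jaccard_distance(a, a) == 0.0

    def test_disjoint_is_one(self):
        a = make_network("a", {"A"})
        b = make_network("b", {"B"})
        assert pc.jaccard_distance(a, b) == 1.0

    def test_direct_formula(self):
        a = make_network("a", {"A", "B", "C"})
        b = make_network("b", {"B", "C", "D"})
        assert pc.jaccard_distance(a, b) == pytest.approx(0.5)

    def test_modes_differ(self):
        a = make_network("a", {"A", "B"}, edges=[("A", "B")])
        b = make_network("b", {"A", "B"})
        assert pc.jaccard_distance(a, b, mode="nodes") == 0.0
        assert pc.jaccard_distance(a, b, mode="nodes+edges") == \
            pytest.approx(1 / 3)
        assert pc.jaccard_distance(a, b, mode="edges") == 1.0
        with pytest.raises(ValueError, match="empty"):
            pc.jaccard_distance(b, b, mode="edges")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 15), min_size=1),
                    min_size=3, max_size=3))
    def test_metric_properties(self, sets):
        nets = [make_network(f"p{i}", {str(x) for x in s})
                for i, s in enumerate(sets)]
        d01 = pc.jaccard_distance(nets[0], nets[1])
        d10 = pc.jaccard_distance(nets[1], nets[0])
        d12 = pc.jaccard_distance(nets[1], nets[2])
        d02 = pc.jaccard_distance(nets[0], nets[2])
        assert d01 == d10
        assert 0.0 <= d01 <= 1.0
        assert d02 <= d01 + d12 + 1e-12


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def square(patients, entries):
    n = len(patients)
    D = np.zeros((n, n))
    for (i, j), v in entries.items():
        D[i, j] = D[j, i] = v
    return D


class TestUpgma:
    def test_three_point_hand_computed(self):
        # d(a,b)=0.1, d(a,c)=d(b,c)=0.8: merge {a,b} at height 0.05,
        # root at 0.4 (d/2 convention)
        D = square(list("abc"), {(0, 1): 0.1, (0, 2): 0.8, (1, 2): 0.8})
        tree = pc.upgma(list("abc"), D)
        first = next(c for c in tree.children if not c.is_leaf)
        assert first.members == {"a", "b"}
        assert first.height == pytest.approx(0.05)
        assert tree.height == pytest.approx(0.4)

    def test_two_patients(self):
        tree = pc.upgma(["a", "b"], square("ab", {(0, 1): 0.6}))
        assert tree.members == {"a", "b"}
        assert all(c.is_leaf for c in tree.children)
        assert tree.height == pytest.approx(0.3)

    def test_equal_distances_all_heights_equal_and_tie_rule(self):
        pats = ["d", "b", "c", "a"]
        D = square(pats, {(i, j): 0.5 for i, j in combinations(range(4), 2)})
        tree = pc.upgma(pats, D)
        heights = [n.height for n in tree.internal_nodes()]
        assert heights == pytest.approx([0.25] * 3)
        # first merge takes the lexicographically earliest pair {a, b}
        first = min(tree.internal_nodes(), key=lambda n: len(n.members))
        assert first.members == {"a", "b"}

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pc.upgma(["a", "b"], np.array([[0, 0.2], [0.3, 0]]))
        with pytest.raises(ValueError, match="at least 2"):
            pc.upgma(["a"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            pc.upgma(["a", "b"], np.array([[0, 1.5], [1.5, 0]]))

    def test_ultrametric_input_reproduced_exactly(self):
        # cophenetic matrix of any dendrogram is ultrametric; feeding it
        # back into UPGMA must reproduce it
        rng = np.random.default_rng(11)
        pts = rng.random((12, 3))
        D = squareform(squareform(np.sqrt(
            ((pts[:, None] - pts[None]) ** 2).sum(-1)))) / 3.0
        pats = [f"p{i:02d}" for i in range(12)]
        base = pc.upgma(pats, D)
        _, C = pc.cophenetic_matrix(base)
        again = pc.upgma(pats, C)
        _, C2 = pc.cophenetic_matrix(again)
        np.testing.assert_allclose(C2, C, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((15, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)) / 4.0
        np.fill_diagonal(D, 0.0)
        pats = [f"p{i:02d}" for i in range(15)]
        tree = pc.upgma(pats, D)
        _, C = pc.cophenetic_matrix(tree)
        Z = linkage(squareform(D), method="average")
        np.testing.assert_allclose(squareform(C), cophenet(Z), atol=1e-10)


# ---------------------------------------------------------------------------
# Cophenetic correlation
# ---------------------------------------------------------------------------

def random_tree(seed, n=8):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)) / 3.0
    np.fill_diagonal(D, 0.0)
    return pc.upgma([f"p{i}" for i in range(n)], D)


class TestCopheneticCorrelation:
    def test_tree_vs_itself(self):
        t = random_tree(3)
        assert pc.cophenetic_correlation(t, t) == pytest.approx(1.0)

    def test_scale_invariance(self):
        t1, t2 = random_tree(4), random_tree(4)
        for node in t2.walk():
            node.height *= 2.0
        assert pc.cophenetic_correlation(t1, t2) == pytest.approx(1.0)

    def test_matches_brute_force_lca_enumeration(self):
        t1, t2 = random_tree(10), random_tree(20)
        leaves = t1.leaves
        v1 = [lca_cophenetic_oracle(t1, p, q)
              for p, q in combinations(leaves, 2)]
        v2 = [lca_cophenetic_oracle(t2, p, q)
              for p, q in combinations(leaves, 2)]
        expected = np.corrcoef(v1, v2)[0, 1]
        assert pc.cophenetic_correlation(t1, t2) == pytest.approx(expected)

    def test_leaf_set_mismatch_is_error(self):
        with pytest.raises(ValueError, match="leaf"):
            pc.cophenetic_correlation(random_tree(1, 8), random_tree(1, 9))


# ---------------------------------------------------------------------------
# Cluster enrichment
# ---------------------------------------------------------------------------

class TestEnumerateClusters:
    def test_perfect_split_matches_exact_hypergeometric(self):
        pats = [f"case{i}" for i in range(10)] + [f"ctrl{i}" for i in range(10)]
        labels = {p: ("case" if p.startswith("case") else "control")
                  for p in pats}
        D = np.full((20, 20), 0.9)
        D[:10, :10] = 0.1
        D[10:, 10:] = 0.1
        np.fill_diagonal(D, 0.0)
        tree = pc.upgma(pats, D)
        records = pc.enumerate_clusters(tree, labels)
        pure = next(r for r in records
                    if r.members == frozenset(pats[:10]))
        expected = fisher_two_sided_oracle(10, 0, 0, 10)
        assert expected == pytest.approx(2 / 184756)  # 2 / C(20,10)
        assert pure.fisher_p == pytest.approx(expected, rel=1e-9)
        assert pure.significant

    def test_composition_matching_cohort_is_nonsignificant(self):
        pats = [f"p{i}" for i in range(8)]
        labels = {p: ("case" if i % 2 == 0 else "control")
                  for i, p in enumerate(pats)}
        D = np.full((8, 8), 0.8)
        D[:4, :4] = 0.1  # p0..p3: 2 cases, 2 controls, same 1:1 ratio
        np.fill_diagonal(D, 0.0)
        tree = pc.upgma(pats, D)
        records = pc.enumerate_clusters(tree, labels)
        half = next(r for r in records if r.members == frozenset(pats[:4]))
        assert half.fisher_p == pytest.approx(1.0)
        assert not half.significant

    def test_17_0_cluster_in_29_32_cohort_is_significant(self):
        # composition mirroring the motivating study's deficient cluster:
        # 17 cases / 0 controls inside a 29-case / 32-control cohort
        cases = [f"case{i:02d}" for i in range(29)]
        ctrls = [f"ctrl{i:02d}" for i in range(32)]
        pats = cases + ctrls
        labels = {p: ("case" if p.startswith("case") else "control")
                  for p in pats}
        D = np.full((61, 61), 0.9)
        D[:17, :17] = 0.1          # tight all-case cluster
        np.fill_diagonal(D, 0.0)
        tree = pc.upgma(pats, D)
        records = pc.enumerate_clusters(tree, labels)
        cluster = next(r for r in records
                       if r.members == frozenset(cases[:17]))
        assert (cluster.n_case, cluster.n_control) == (17, 0)
        expected = fisher_two_sided_oracle(17, 0, 12, 32)
        assert cluster.fisher_p == pytest.approx(expected, rel=1e-9)
        assert cluster.significant

    def test_unlabeled_leaf_is_error(self):
        tree = pc.upgma(["a", "b"], square("ab", {(0, 1): 0.5}))
        with pytest.raises(ValueError, match="unlabeled"):
            pc.enumerate_clusters(tree, {"a": "case"})

    def test_dominated_cluster_selection_rule(self):
        mk = lambda node, nc, nn, p: pc.ClusterRecord(
            node=node, members=frozenset(f"{node}{i}" for i in range(nc + nn)),
            n_case=nc, n_control=nn, fisher_p=p, significant=True)
        recs = [mk("A", 5, 0, 0.01), mk("B", 7, 0, 0.02),
                mk("C", 7, 0, 0.01), mk("D", 1, 9, 0.001)]
        best = pc.dominated_clusters(recs, "case")
        assert [r.node for r in best[:2]] == ["C", "B"]  # more cases, then p
        assert pc.dominated_clusters(recs, "control")[0].node == "D"


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def test_newick_roundtrips_through_dendropy():
    import dendropy

    tree = random_tree(6, n=7)
    labels = {p: ("case" if i % 2 else "control")
              for i, p in enumerate(tree.leaves)}
    pc.enumerate_clusters(tree, labels)
    nwk = pc.to_newick(tree)
    parsed = dendropy.Tree.get(data=nwk, schema="newick")
    taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
    assert taxa == set(tree.leaves)
    # ultrametric: root-to-leaf depth equals root height for every leaf
    # (up to the 6-significant-digit branch-length formatting)
    depths = [leaf.distance_from_root()
              for leaf in parsed.leaf_node_iter()]
    assert depths == pytest.approx([tree.height] * len(depths), abs=1e-4)


# ---------------------------------------------------------------------------
# Seed-count selection
# ---------------------------------------------------------------------------

class TestSelectSeedCount:
    def test_table_shape_and_choice(self, planted_cohort):
        patients = sorted(planted_cohort.labels)[:25]
        ks = [25, 50, 100]
        chosen, table = pc.select_seed_count(
            planted_cohort.expression, patients, ks,
            planted_cohort.interactome)
        assert list(table.index) == ks
        np.testing.assert_allclose(np.diag(table), 1.0)
        np.testing.assert_allclose(table, table.T)
        assert chosen in ks

    def test_identical_k_gives_correlation_one(self, planted_cohort):
        patients = sorted(planted_cohort.labels)[:15]
        nets = pc.build_all_networks(
            planted_cohort.expression, patients,
            planted_cohort.interactome, 30)
        pats, D = pc.similarity_matrix(nets)
        t1, t2 = pc.upgma(pats, D), pc.upgma(pats, D)
        assert pc.cophenetic_correlation(t1, t2) == pytest.approx(1.0)

    def test_oversized_k_dropped_with_warning(self, planted_cohort):
        patients = sorted(planted_cohort.labels)[:10]
        n_genes = planted_cohort.expression.shape[1]
        chosen, table = pc.select_seed_count(
            planted_cohort.expression, patients, [20, 40, n_genes + 5],
            planted_cohort.interactome)
        assert list(table.index) == [20, 40]

    def test_too_few_candidates_is_error(self, planted_cohort):
        with pytest.raises(ValueError, match="at least 2"):
            pc.select_seed_count(planted_cohort.expression, [], [100],
                                 planted_cohort.interactome)
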