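"""Local-alignment edges, reciprocal best hits, Markov clustering and pair
calling."""

import itertools

import numpy as np
import pytest

from famcensus import homology as hm
from famcensus import synthetic_data as sd

AA = sd.AMINO_ACIDS


def sw_oracle(a, b, go=10.0, ge=0.5):
    """Independent Smith-Waterman: exhaustive DP, gap of length k costs
    go + k*ge."""
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    la, lb = len(a), len(b)
    M = np.zeros((la + 1, lb + 1))
    X = np.full((la + 1, lb + 1), -1e30)
    Y = np.full((la + 1, lb + 1), -1e30)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i, j] = max(M[i, j - 1] - go - ge, X[i, j - 1] - ge)
            Y[i, j] = max(M[i - 1, j] - go - ge, Y[i - 1, j] - ge)
            M[i, j] = max(0.0,
                          m[a[i - 1], b[j - 1]]
                          + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                Y[i - 1, j - 1]))
            best = max(best, M[i, j])
    return best


class TestAllVsAll:
    def test_identical_sequences_have_weight_one(self):
        edges = hm.all_vs_all({"a": "MKLVWWGGAEDD"}, {"b": "MKLVWWGGAEDD"},
                              min_score=1.0)
        (e,) = edges
        assert e.weight == pytest.approx(1.0)

    def test_scores_match_independent_local_dp_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            a = "".join(rng.choice(list(AA), rng.integers(4, 13)))
            b = "".join(rng.choice(list(AA), rng.integers(4, 13)))
            assert hm.local_score(a, b) == pytest.approx(sw_oracle(a, b))

    def test_null_threshold_excludes_unrelated_sequences(self):
        rng = np.random.default_rng(3)
        A = {f"a{i}": "".join(rng.choice(list(AA), 120)) for i in range(4)}
        B = {f"b{i}": "".join(rng.choice(list(AA), 120)) for i in range(4)}
        thr = hm.calibrate_min_score({**A, **B}, n_pairs=60, seed=3)
        edges = hm.all_vs_all(A, B, min_score=thr * 1.3)
        assert edges == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hm.all_vs_all({}, {"b": "MKL"})

    def test_weights_invariant_to_set_ordering(self):
        seqs = {"a": "MKLVWWGGAEDD", "b": "MKLVWWGGAEDA", "c": "PPQRSTVVNMKL"}
        e1 = hm.all_vs_all(seqs, seqs, min_score=1.0)
        rev = dict(reversed(list(seqs.items())))
        e2 = hm.all_vs_all(rev, rev, min_score=1.0)
        assert e1 == e2


def brute_force_rbh(W):
    """All mutual-unique-argmax pairs of a weight matrix (0 = no edge)."""
    na, nb = W.shape
    pairs = set()
    for i in range(na):
        for j in range(nb):
            if W[i, j] <= 0:
                continue
            row_best = W[i, j] == W[i].max() and (W[i] == W[i].max()).sum() == 1
            col_best = (W[i, j] == W[:, j].max()
                        and (W[:, j] == W[:, j].max()).sum() == 1)
            if row_best and col_best:
                pairs.add((f"a{i}", f"b{j}"))
    return pairs


def edges_from_matrix(W):
    edges = []
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            if W[i, j] > 0:
                edges.append(hm.Edge(f"a{i}", f"b{j}", float(W[i, j])))
    return edges


SPECIES_4x4 = {**{f"a{i}": "A" for i in range(4)},
               **{f"b{j}": "B" for j in range(4)}}


class TestRBH:
    def test_worked_two_by_two_example(self):
        W = np.array([[0.9, 0.2], [0.3, 0.8]])
        got = {(e.a, e.b) for e in hm.rbh(edges_from_matrix(W), SPECIES_4x4)}
        assert got == {("a0", "b0"), ("a1", "b1")}

    def test_non_reciprocal_best_yields_no_pair(self):
        W = np.array([[0.5, 0.0], [0.9, 0.0]])
        # a0's best is b0, but b0's best is a1
        got = {(e.a, e.b) for e in hm.rbh(edges_from_matrix(W), SPECIES_4x4)}
        assert got == {("a1", "b0")}

    def test_exact_tie_for_best_is_excluded(self):
        W = np.array([[0.7, 0.7], [0.0, 0.0]])
        assert hm.rbh(edges_from_matrix(W), SPECIES_4x4) == []

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            na, nb = rng.integers(1, 5, 2)
            W = np.round(rng.random((na, nb)), 2)
            W[rng.random((na, nb)) < 0.3] = 0.0
            got = {(e.a, e.b)
                   for e in hm.rbh(edges_from_matrix(W), SPECIES_4x4)}
            assert got == brute_force_rbh(W)


def clique_edges(nodes, weight=1.0):
    return [hm.Edge(a, b, weight)
            for a, b in itertools.combinations(sorted(nodes), 2)]


class TestMCL:
    def test_disjoint_triangles_give_two_clusters(self):
        edges = clique_edges("abc") + clique_edges("xyz")
        clusters = hm.mcl(list("abcxyz"), edges)
        assert sorted(map(sorted, clusters)) == [list("abc"), list("xyz")]

    def test_single_edge_is_one_cluster(self):
        clusters = hm.mcl(["a", "b"], [hm.Edge("a", "b", 1.0)])
        assert clusters == [{"a", "b"}]

    def test_weak_bridge_between_cliques_splits(self):
        edges = (clique_edges("abcd") + clique_edges("wxyz")
                 + [hm.Edge("d", "w", 0.05)])
        clusters = hm.mcl(list("abcdwxyz"), edges, inflation=2.0)
        assert sorted(map(sorted, clusters)) == [list("abcd"), list("wxyz")]

    def test_output_is_a_partition_invariant_to_node_order(self):
        edges = clique_edges("abc") + clique_edges("pq") + [
            hm.Edge("c", "p", 0.1)]
        nodes = list("abcpq")
        c1 = hm.mcl(nodes, edges)
        c2 = hm.mcl(list(reversed(nodes)), edges)
        flat = sorted(n for c in c1 for n in c)
        assert flat == sorted(nodes)
        assert sorted(map(sorted, c1)) == sorted(map(sorted, c2))


class TestCallPairs:
    def test_planted_families_recovered_at_zero_noise(self):
        # two families, each with one query member pair and one anchor
        spec = sd.FamilySpec(counts_per_class={"2R3R": 4},
                             groups_per_class={"2R3R": 2},
                             unanchored_groups={}, anchors_per_group=1,
                             substitution_rate=0.0, seed=12)
        b = sd.generate_proteome(spec)
        pool = {**b.proteins, **b.anchors}
        species = {**{p: "query" for p in b.proteins},
                   **{a: "reference" for a in b.anchors}}
        edges = hm.all_vs_all(pool, pool, min_score=50.0)
        clusters = hm.mcl(sorted(pool), edges)
        orthologs, paralogs = hm.call_pairs(clusters, edges, species)
        fam = {p: t.family for p, t in b.truth.proteins.items()}
        for a in b.anchors:
            fam[a] = int(a[3:6])
        # every cluster is family-pure and paralog pairs stay within family
        for c in clusters:
            assert len({fam[n] for n in c}) == 1
        for pairs in paralogs.values():
            for e in pairs:
                assert fam[e.a] == fam[e.b]
        # each anchor pairs with exactly one member of its own family
        assert len(orthologs) <= len(b.anchors)
        for e in orthologs:
            assert fam[e.a] == fam[e.b]

    def test_ortholog_pairs_never_exceed_rbh_pairs(self):
        rng = np.random.default_rng(9)
        W = rng.random((4, 4))
        edges = edges_from_matrix(W)
        rbh_pairs = hm.rbh(edges, SPECIES_4x4)
        clusters = hm.mcl(sorted(SPECIES_4x4), edges)
        orthologs, _ = hm.call_pairs(clusters, edges, SPECIES_4x4,
                                     rbh_pairs=rbh_pairs)
        assert len(orthologs) <= len(rbh_pairs)

    def test_gene_may_appear_in_multiple_paralog_pairs(self):
        # one species triangle within a cluster: a node joins several pairs
        edges = clique_edges("abc", weight=0.9)
        species = {n: "A" for n in "abc"}
        clusters = [{"a", "b", "c"}]
        _, paralogs = hm.call_pairs(clusters, edges, species)
        per_node = {}
        for e in paralogs["A"]:
            per_node[e.a] = per_node.get(e.a, 0) + 1
            per_node[e.b] = per_node.get(e.b, 0) + 1
        assert max(per_node.values()) >= 2
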