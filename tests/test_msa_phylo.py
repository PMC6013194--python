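"""Alignment, neighbour joining, bootstrap and anchor-guided grouping."""

import itertools

import numpy as np
import pytest

from famcensus import msa_phylo as mp
from famcensus import synthetic_data as sd

AA = sd.AMINO_ACIDS


def _biopython_global(a, b, go=10.0, ge=0.5):
    from Bio import Align
    from Bio.Align import substitution_matrices
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -(go + ge)
    al.extend_gap_score = -ge
    return al.score(a, b)


class TestPairwiseAlign:
    def test_identical_sequences_score_diagonal_and_no_gaps(self):
        from Bio.Align import substitution_matrices
        m = substitution_matrices.load("BLOSUM62")
        s = "ACDEFGHIKL"
        score, (a, b) = mp.pairwise_align(s, s)
        assert score == pytest.approx(sum(m[c, c] for c in s))
        assert a == b == s

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mp.pairwise_align("A", "")

    def test_matches_independent_dp_oracle_on_random_toys(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = "".join(rng.choice(list(AA), rng.integers(3, 13)))
            b = "".join(rng.choice(list(AA), rng.integers(3, 13)))
            score, (ga, gb) = mp.pairwise_align(a, b)
            assert score == pytest.approx(_biopython_global(a, b), abs=1e-6)
            # reported alignment is consistent with the reported score
            from Bio.Align import substitution_matrices
            m = substitution_matrices.load("BLOSUM62")
            total, gap = 0.0, 0
            for x, y in zip(ga, gb):
                if x == "-" or y == "-":
                    total -= 0.5 + (10.0 if gap == 0 else 0.0)
                    gap += 1
                else:
                    total += m[x, y]
                    gap = 0
            assert total == pytest.approx(score, abs=1e-6)


class TestProgressiveMSA:
    def test_identical_sequences_align_gap_free(self):
        aln = mp.progressive_msa({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL",
                                  "c": "ACDEFGHIKL"})
        assert all(s == "ACDEFGHIKL" for _, s in aln.records)

    def test_disjoint_single_substitutions_stay_gap_free(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        variants = {}
        for i, pos in enumerate([2, 7, 12]):
            s = list(base)
            s[pos] = "W" if s[pos] != "W" else "Y"
            variants[f"v{i}"] = "".join(s)
        aln = mp.progressive_msa(variants)
        assert aln.width == len(base)
        assert all("-" not in s for _, s in aln.records)

    def test_invariant_to_input_order_up_to_row_order(self):
        seqs = {"a": "ACDEFGHIKLMNP", "b": "ACDEFGHIKLMNQ",
                "c": "ACDEWGHIKLMNP", "d": "MNPQRSTVWYACD"}
        a1 = mp.progressive_msa(seqs)
        a2 = mp.progressive_msa(dict(reversed(list(seqs.items()))))
        assert dict(a1.records) == dict(a2.records)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            mp.progressive_msa({"a": "ACDE"})


class TestDistanceMatrix:
    def test_identical_rows_are_zero(self):
        D = mp.distance_matrix(mp.Alignment([("a", "ACDE"), ("b", "ACDE")]))
        assert D.matrix[0, 1] == 0.0

    def test_single_mismatch_fraction(self):
        D = mp.distance_matrix(mp.Alignment([("a", "AAAA"), ("b", "AAAT")]))
        assert D.matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_compares_ungapped_sites_only(self):
        D = mp.distance_matrix(mp.Alignment([("a", "A-CA"), ("b", "AGCA")]))
        assert D.matrix[0, 1] == 0.0  # 3 comparable sites, all equal

    def test_zero_comparable_sites_errors_naming_pair(self):
        with pytest.raises(mp.DataError, match="a.*b"):
            mp.distance_matrix(mp.Alignment([("a", "A--A"), ("b", "-GG-")]))


def tree_metric(n_taxa, rng):
    """Generate a random additive matrix by explicit tree simulation."""
    # nodes: list of (leafset dict leaf->dist)
    groups = [{f"t{i}": 0.0} for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    names = [f"t{i}" for i in range(n_taxa)]
    idx = {n: i for i, n in enumerate(names)}
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), 2, replace=False))
        g2, g1 = groups.pop(j), groups.pop(i)
        l1, l2 = rng.uniform(0.5, 2.0, 2)
        for a, da in g1.items():
            for b, db in g2.items():
                D[idx[a], idx[b]] = D[idx[b], idx[a]] = da + l1 + db + l2
        merged = {a: d + l1 for a, d in g1.items()}
        merged.update({b: d + l2 for b, d in g2.items()})
        groups.append(merged)
    return names, D


class TestNJTree:
    def test_four_taxon_worked_example(self):
        labels = list("ABCD")
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = mp.nj_tree(mp.DistanceMatrix(labels, D))
        # topology: A,B form a cherry separated from C,D
        bips = {frozenset(k) for k in tree.bipartitions()}
        assert frozenset({"A", "B"}) in bips or frozenset({"C", "D"}) in bips
        # leaf branch lengths 1,2,3,4 and internal branch 1
        leaf_bl = {c.name: bl for _, c, bl in tree._edges() if c.is_leaf()}
        assert leaf_bl == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        internal = [bl for _, c, bl in tree._edges() if not c.is_leaf()]
        assert internal == pytest.approx([1.0])
        leaves, P = tree.patristic_distances()
        assert np.allclose(P, D)

    def test_additive_matrices_round_trip_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            names, D = tree_metric(n, rng)
            tree = mp.nj_tree(mp.DistanceMatrix(names, D))
            leaves, P = tree.patristic_distances()
            order = [names.index(l) for l in leaves]
            assert np.allclose(P, D[np.ix_(order, order)], atol=1e-8)

    def test_matches_scikit_bio_topology(self):
        import skbio
        rng = np.random.default_rng(23)
        names, D = tree_metric(7, rng)
        ours = mp.nj_tree(mp.DistanceMatrix(names, D))
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=names))
        ref_bips = set()
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(names) - 2:
                key = side if "t0" not in side else frozenset(names) - side
                ref_bips.add(key)
        assert set(ours.bipartitions()) == ref_bips

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            mp.nj_tree(mp.DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_star_matrix_gives_equal_path_lengths(self):
        names = list("ABCDE")
        D = np.full((5, 5), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = mp.nj_tree(mp.DistanceMatrix(names, D))
        _, P = tree.patristic_distances()
        off = P[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 2.0)


def four_taxon_alignment(n_ab, n_ac, width_pad=0):
    """Columns supporting AB|CD vs AC|BD."""
    cols = []
    for _ in range(n_ab):
        cols.append(("A", "A", "C", "C"))
    for _ in range(n_ac):
        cols.append(("A", "C", "A", "C"))
    rows = ["".join(c[i] for c in cols) for i in range(4)]
    return mp.Alignment(list(zip("abcd", rows)))


class TestBootstrap:
    def test_unanimous_signal_gives_support_100(self):
        aln = four_taxon_alignment(12, 0)
        tree, supports = mp.bootstrap_supports(aln, n_reps=50, seed=1)
        assert all(v == 100.0 for v in supports.values())

    def test_single_replicate_supports_are_zero_or_hundred(self):
        aln = four_taxon_alignment(8, 4)
        _, supports = mp.bootstrap_supports(aln, n_reps=1, seed=2)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_conflicting_signal_matches_enumeration(self):
        # half the columns support ab|cd, half ac|bd; enumerate the exact
        # resample distribution over AB-column counts to get the expected
        # support of the reference tree's internal edge
        from math import comb
        width = 12
        aln = four_taxon_alignment(6, 6)
        ref = mp.nj_tree(mp.distance_matrix(aln))
        (ref_bip,) = list(ref.bipartitions())

        def topo_for(k_ab):
            a = four_taxon_alignment(k_ab, width - k_ab)
            t = mp.nj_tree(mp.distance_matrix(a))
            return set(t.bipartitions())

        expected = 0.0
        for k in range(width + 1):
            p = comb(width, k) * 0.5 ** width
            if ref_bip in topo_for(k):
                expected += 100.0 * p
        _, supports = mp.bootstrap_supports(aln, n_reps=1000, seed=3)
        assert supports[ref_bip] == pytest.approx(expected, abs=5.0)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            mp.bootstrap_supports(mp.Alignment([("a", ""), ("b", "")]), 10)


@pytest.fixture(scope="module")
def grouped_bundle():
    spec = sd.FamilySpec(seed=5)
    b = sd.generate_proteome(spec)
    myb = {p: s for p, s in b.proteins.items()
           if b.truth.proteins[p].architecture != "NONE"}
    a1 = {a: s for a, s in b.anchors.items()
          if b.anchor_labels[a][0] in ("R2R3", "R1R2R3")}
    l1 = {a: b.anchor_labels[a][1] for a in a1}
    a2 = {a: s for a, s in b.anchors.items() if a not in a1}
    l2 = {a: b.anchor_labels[a][1] for a in a2}
    return b, myb, (a1, l1), (a2, l2)


class TestAssignGroups:
    def test_query_sister_to_single_anchor_takes_its_label(self):
        # manual tree: (query, anchorX) cherry far from the rest
        q = mp.TreeNode(name="q")
        ax = mp.TreeNode(name="ax")
        other1 = mp.TreeNode(name="a1")
        other2 = mp.TreeNode(name="a2")
        cherry = mp.TreeNode(children=[(q, 0.1), (ax, 0.1)])
        root = mp.TreeNode(children=[(cherry, 1.0), (other1, 1.0),
                                     (other2, 1.0)])
        tree = mp.Tree(root)
        out = mp.assign_groups(tree, {"ax": "C9", "a1": "C1", "a2": "C1"})
        assert out["q"].group == "C9"

    def test_distant_query_called_species_specific(self):
        q = mp.TreeNode(name="q")
        a1 = mp.TreeNode(name="a1")
        a2 = mp.TreeNode(name="a2")
        a3 = mp.TreeNode(name="a3")
        cherry = mp.TreeNode(children=[(a1, 0.05), (a2, 0.05)])
        root = mp.TreeNode(children=[(cherry, 0.05), (a3, 0.05), (q, 50.0)])
        out = mp.assign_groups(mp.Tree(root),
                               {"a1": "G", "a2": "G", "a3": "G"})
        assert out["q"].group == sd.SPECIES_SPECIFIC

    def test_no_anchors_rejected(self):
        t = mp.Tree(mp.TreeNode(children=[
            (mp.TreeNode(name="x"), 1.0), (mp.TreeNode(name="y"), 1.0),
            (mp.TreeNode(name="z"), 1.0)]))
        with pytest.raises(ValueError):
            mp.assign_groups(t, {})


class TestTwoStage:
    def test_zero_noise_label_recovery_is_perfect(self):
        spec = sd.FamilySpec(
            counts_per_class={"2R3R": 12, "1R": 8},
            groups_per_class={"2R3R": 3, "1R": 2},
            unanchored_groups={}, substitution_rate=0.0, seed=8)
        b = sd.generate_proteome(spec)
        myb = dict(b.proteins)
        a1 = {a: s for a, s in b.anchors.items()
              if b.anchor_labels[a][0] == "R2R3"}
        l1 = {a: b.anchor_labels[a][1] for a in a1}
        a2 = {a: s for a, s in b.anchors.items() if a not in a1}
        l2 = {a: b.anchor_labels[a][1] for a in a2}
        res = mp.two_stage_classify(myb, (a1, l1), (a2, l2))
        for q in myb:
            assert res.assignments[q].group == b.truth.proteins[q].group

    def test_stage2_input_is_total_minus_stage1_labeled(self, grouped_bundle):
        _, myb, anchors1, anchors2 = grouped_bundle
        res = mp.two_stage_classify(myb, anchors1, anchors2)
        assert res.stage2_input == len(myb) - res.stage1_labeled
        assert set(res.assignments) == set(myb)

    def test_overlapping_anchor_sets_rejected(self, grouped_bundle):
        _, myb, (a1, l1), _ = grouped_bundle
        with pytest.raises(ValueError):
            mp.two_stage_classify(myb, (a1, l1), (a1, l1))
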