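"""Neighbour joining, bootstrap supports, newick and tree-based assignment."""

import numpy as np
import pytest

import dendropy

from oracles import naive_nj_bipartitions, random_additive_tree
from scombkey.distances import DistanceMatrix, P_DISTANCE, build_distance_matrix
from scombkey.njtree import (
    AMBIGUOUS_BETWEEN_CLUSTERS,
    PhyloTree,
    TreeError,
    assign_by_tree,
    bootstrap_supports,
    nj_build,
    to_newick,
)
from scombkey.seqio import Alignment, SequenceRecord


def _dm(labels, rows):
    return DistanceMatrix(tuple(labels), np.array(rows, dtype=float), P_DISTANCE)


def _aln(pairs):
    return Alignment([SequenceRecord(i, s) for i, s in pairs])


def _recovered_lengths(tree: PhyloTree):
    """Pendant lengths keyed by leaf, internal lengths keyed by canonical block."""
    out = {}
    for node in tree.root.walk():
        if node is tree.root:
            continue
        if node.is_leaf:
            out[node.name] = node.length
        else:
            out[tree._canonical(node.leaf_names())] = node.length
    return out


class TestNJBuild:
    def test_three_taxa_closed_form(self):
        # l_A = (d_AB + d_AC - d_BC)/2, etc.
        dm = _dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_build(dm)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_recovery(self):
        # path metric of ((A:1,B:2):1,(C:3,D:4)) joined by a unit inner edge
        dm = _dm(
            "ABCD",
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        tree = nj_build(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        lengths = _recovered_lengths(tree)
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert lengths["D"] == pytest.approx(4.0)
        assert lengths[frozenset({"C", "D"})] == pytest.approx(1.0)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            labels, D, biparts, lengths = random_additive_tree(n, rng)
            tree = nj_build(_dm(labels, D))
            assert tree.bipartitions() == biparts
            rec = _recovered_lengths(tree)
            for key, expected in lengths.items():
                assert rec[key] == pytest.approx(expected, abs=1e-9)

    def test_equal_distances_deterministic_tie_break(self):
        dm = _dm("ABCD", (np.ones((4, 4)) - np.eye(4)).tolist())
        t1, t2 = nj_build(dm), nj_build(dm)
        assert to_newick(t1) == to_newick(t2)
        # lowest (row, col) pair joins first: A and B
        assert t1.bipartitions() <= {frozenset({"C", "D"})}

    def test_too_few_taxa(self):
        with pytest.raises(TreeError):
            nj_build(_dm("AB", [[0, 1], [1, 0]]))

    def test_non_finite_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.inf
        with pytest.raises(TreeError, match="finite"):
            nj_build(DistanceMatrix(("a", "b", "c"), m, P_DISTANCE))

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            labels, D, _, _ = random_additive_tree(8, rng)
            noisy = D + rng.uniform(-0.05, 0.05, D.shape)
            noisy = np.triu(noisy, 1)
            noisy = noisy + noisy.T
            np.fill_diagonal(noisy, 0.0)
            noisy = np.abs(noisy)
            tree = nj_build(_dm(labels, noisy))
            assert all(
                n.length >= 0.0 for n in tree.root.walk() if n is not tree.root
            )

    def test_matches_independent_nj_on_random_matrix(self):
        # scikit-bio's NJ as an independent implementation (topology check)
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        labels, D, _, _ = random_additive_tree(8, rng)
        D = (D + D.T) / 2.0  # exact symmetry for skbio's strict validation
        sk_tree = skbio.tree.nj(
            skbio.DistanceMatrix(D, ids=labels)
        )
        sk_biparts = set()
        n = len(labels)
        anchor = min(labels)
        for node in sk_tree.non_tips(include_self=False):
            block = frozenset(t.name for t in node.tips())
            if 2 <= len(block) <= n - 2:
                if anchor in block:
                    block = frozenset(labels) - block
                sk_biparts.add(block)
        assert nj_build(_dm(labels, D)).bipartitions() == sk_biparts


class TestNewick:
    def test_three_leaf_shape(self):
        t = nj_build(_dm("ABC", [[0, 2, 2], [2, 0, 2], [2, 2, 0]]))
        text = to_newick(t)
        assert text.startswith("(") and text.endswith(";")
        assert "A:1" in text

    def test_round_trip_preserves_bipartitions_and_supports(self):
        # small alignment with clean structure; supports present
        aln = _aln(
            [
                ("A1", "AAAAAAAACC"),
                ("A2", "AAAAAAAACG"),
                ("B1", "TTTTTTTTCC"),
                ("B2", "TTTTTTTTGC"),
                ("C1", "GGGGGGGGAA"),
            ]
        )
        tree = bootstrap_supports(aln, n_reps=20, seed=1)
        text = to_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        parsed.encode_bipartitions()
        leafset = frozenset(l.taxon.label for l in parsed.leaf_node_iter())
        anchor = min(leafset)
        parsed_biparts = {}
        for node in parsed.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            block = frozenset(l.taxon.label for l in node.leaf_iter())
            if not 2 <= len(block) <= len(leafset) - 2:
                continue
            if anchor in block:
                block = leafset - block
            support = float(node.label) if node.label else None
            parsed_biparts[block] = support
        assert set(parsed_biparts) == tree.bipartitions()
        for block, support in tree.supports().items():
            assert parsed_biparts[block] == pytest.approx(support)


class TestBootstrap:
    def test_unanimous_split_gets_support_100(self):
        aln = _aln(
            [
                ("A", "AAAAAAAAAA"),
                ("B", "AAAAAAAAAA"),
                ("C", "TTTTTTTTTT"),
                ("D", "TTTTTTTTTT"),
            ]
        )
        tree = bootstrap_supports(aln, n_reps=100, seed=0)
        supports = tree.supports()
        assert supports[frozenset({"C", "D"})] == 100.0

    def test_fixed_seed_bitwise_identical(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(6)]
        aln = _aln([(f"t{i}", s) for i, s in enumerate(seqs)])
        t1 = bootstrap_supports(aln, n_reps=30, seed=77)
        t2 = bootstrap_supports(aln, n_reps=30, seed=77)
        assert to_newick(t1) == to_newick(t2)

    def test_supports_match_naive_recount_of_shared_stream(self):
        # three clean pairs; the naive recount consumes the same index stream
        rng = np.random.default_rng(4)
        base = {
            "A": "A" * 20,
            "B": "C" * 20,
            "C": "G" * 20,
        }
        pairs = []
        for grp, seq in base.items():
            noise = list(seq)
            noise[3] = "T"
            pairs += [(f"{grp}1", seq + "ACGTACGTAC"),
                      (f"{grp}2", "".join(noise) + "ACGTACGTAC")]
        aln = _aln(pairs)
        n_reps, seed = 50, 123
        tree = bootstrap_supports(aln, n_reps=n_reps, seed=seed)

        codes = [r.seq for r in aln]
        labels = [r.id for r in aln]
        stream = np.random.default_rng(seed)
        counts: dict = {}
        from oracles import naive_distance_matrix

        for _ in range(n_reps):
            idx = stream.integers(0, aln.length, size=aln.length)
            seqs = ["".join(s[k] for k in idx) for s in codes]
            D = naive_distance_matrix(seqs, "p")
            for block in naive_nj_bipartitions(labels, D):
                counts[block] = counts.get(block, 0) + 1
        expected = {
            block: 100.0 * counts.get(block, 0) / n_reps
            for block in tree.bipartitions()
        }
        assert tree.supports() == pytest.approx(expected)

    def test_supports_within_bounds(self, default_panel):
        aln = Alignment(default_panel.alignment.records[:12])
        tree = bootstrap_supports(aln, n_reps=25, seed=5)
        assert all(0.0 <= s <= 100.0 for s in tree.supports().values())


class TestAssignByTree:
    def test_query_in_monospecific_cluster(self):
        aln = _aln(
            [
                ("r1", "AAAAAAAAAA"),
                ("r2", "AAAAAAAACC"),
                ("s1", "TTTTTTTTTT"),
                ("s2", "TTTTTTTTGG"),
                ("q", "AAAAAAAACG"),  # inside the X cluster, nearest r2
            ]
        )
        tree = nj_build(build_distance_matrix(aln))
        res = assign_by_tree(
            tree, {"r1": "X", "r2": "X", "s1": "Y", "s2": "Y"}, ["q"]
        )
        assert res["q"].species == "X"
        assert res["q"].flag is None

    def test_query_between_clusters_is_ambiguous(self):
        # q equidistant from both two-reference clusters on a symmetric metric
        labels = ["a1", "a2", "b1", "b2", "q"]
        D = np.array(
            [
                [0.0, 0.2, 1.0, 1.0, 0.6],
                [0.2, 0.0, 1.0, 1.0, 0.6],
                [1.0, 1.0, 0.0, 0.2, 0.6],
                [1.0, 1.0, 0.2, 0.0, 0.6],
                [0.6, 0.6, 0.6, 0.6, 0.0],
            ]
        )
        tree = nj_build(DistanceMatrix(tuple(labels), D, P_DISTANCE))
        res = assign_by_tree(
            tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, ["q"]
        )
        assert res["q"].species is None
        assert res["q"].flag == AMBIGUOUS_BETWEEN_CLUSTERS
        assert res["q"].candidates == ("A", "B")

    def test_missing_query_rejected(self):
        tree = nj_build(_dm("ABC", [[0, 1, 1], [1, 0, 1], [1, 1, 0]]))
        with pytest.raises(TreeError, match="absent"):
            assign_by_tree(tree, {"A": "X"}, ["nope"])
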