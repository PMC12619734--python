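"""Distance matrices, neighbor joining, monophyly tests."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from jumboclade import phylo, sim


def _path_distances(tree):
    tips = sorted(tree.tips(), key=lambda t: t.name)
    out = {}
    for a, b in itertools.combinations(tips, 2):
        out[(a.name, b.name)] = a.distance(b)
    return out


class TestMarkerDistances:
    def test_identical_sequences_zero_matrix(self):
        dm = phylo.marker_distance_matrix(
            {t: "MKLVWYHHEE" for t in ("a", "b", "c")})
        np.testing.assert_allclose(dm.data, np.zeros((3, 3)))

    def test_unrelated_sequence_near_one(self):
        dm = phylo.marker_distance_matrix(
            {"a": "MKLVWY" * 10, "b": "MKLVWY" * 10, "c": "AAAAGG" * 10})
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] > 0.5

    def test_matrix_matches_pairwise_recomputation(self, small_clade):
        from jumboclade import homology
        members = {gid: small_clade.genes[gid][0].protein
                   for gid in small_clade.genes}
        dm = phylo.marker_distance_matrix(members)
        for a, b in itertools.combinations(sorted(members), 2):
            aln = homology.align_local(members[a], members[b])
            expected = 1 - aln.pct_identity / 100 if aln else 1.0
            assert dm[a, b] == pytest.approx(expected)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.marker_distance_matrix({"a": "MKLV", "b": "MKLV"})


class TestNeighborJoining:
    def test_exact_on_additive_four_taxon_matrix(self):
        # path distances of ((A:1,B:2):1,(C:3,D:4))
        dm = DistanceMatrix(
            np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float),
            ids=list("ABCD"))
        tree = phylo.neighbor_joining(dm)
        assert phylo.is_monophyletic(tree, {"A", "B"})
        assert phylo.is_monophyletic(tree, {"C", "D"})
        dists = _path_distances(tree)
        for (a, b), d in dists.items():
            assert d == pytest.approx(dm[a, b], abs=1e-9)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]],
                                     dtype=float), ids=list("abc"))
        tree = phylo.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_additive_matrices_reproduced_to_tolerance(self):
        # random additive matrix from a fixed 6-taxon tree
        source = TreeNode.read(
            ["((A:0.1,B:0.25):0.3,(C:0.2,(D:0.15,E:0.05):0.4):0.1,F:0.5);"])
        tips = sorted(source.tips(), key=lambda t: t.name)
        ids = [t.name for t in tips]
        mat = np.zeros((6, 6))
        for i, a in enumerate(tips):
            for j, b in enumerate(tips):
                if i < j:
                    mat[i, j] = mat[j, i] = a.distance(b)
        dm = DistanceMatrix(mat, ids=ids)
        tree = phylo.neighbor_joining(dm)
        for (a, b), d in _path_distances(tree).items():
            assert d == pytest.approx(dm[a, b], abs=1e-9)

    def test_agrees_with_library_nj_topology(self):
        source = TreeNode.read(
            ["((A:0.1,B:0.25):0.3,(C:0.2,(D:0.15,E:0.05):0.4):0.1,F:0.5);"])
        tips = sorted(source.tips(), key=lambda t: t.name)
        ids = [t.name for t in tips]
        mat = np.zeros((6, 6))
        for i, a in enumerate(tips):
            for j, b in enumerate(tips):
                if i < j:
                    mat[i, j] = mat[j, i] = a.distance(b)
        dm = DistanceMatrix(mat, ids=ids)
        ours = phylo.neighbor_joining(dm)
        theirs = skbio_nj(dm)
        assert ours.compare_rfd(theirs) == 0.0

    def test_deterministic_on_ties(self):
        # equidistant taxa: any resolution valid, output must be stable
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("wxyz"))
        t1 = phylo.neighbor_joining(dm)
        t2 = phylo.neighbor_joining(dm)
        assert str(t1) == str(t2)

    def test_negative_branch_lengths_clamped(self, caplog):
        dm = DistanceMatrix(np.array(
            [[0, 1, 10, 10], [1, 0, 10, 10],
             [10, 10, 0, 1], [10, 10, 1, 0]], dtype=float), ids=list("abcd"))
        tree = phylo.neighbor_joining(dm)
        assert all(t.length >= 0 for t in tree.traverse() if t.length is not None)

    def test_newick_round_trip_idempotent(self, tmp_path):
        dm = DistanceMatrix(np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                                      [5, 6, 0, 7], [6, 7, 7, 0]],
                                     dtype=float), ids=list("ABCD"))
        tree = phylo.neighbor_joining(dm)
        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        tree.write(str(p1))
        TreeNode.read(str(p1)).write(str(p2))
        assert p1.read_text() == p2.read_text()


class TestMonophyly:
    @pytest.fixture()
    def tree(self):
        return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1,E:1);"])

    def test_all_leaves_monophyletic(self, tree):
        assert phylo.is_monophyletic(tree, {"A", "B", "C", "D", "E"})

    def test_single_leaf_monophyletic(self, tree):
        assert phylo.is_monophyletic(tree, {"C"})

    def test_clade_found(self, tree):
        assert phylo.is_monophyletic(tree, {"A", "B"})
        assert not phylo.is_monophyletic(tree, {"A", "C"})

    def test_complement_side_counts(self, tree):
        # {C, D, E} is one side of the A,B edge on an unrooted tree
        assert phylo.is_monophyletic(tree, {"C", "D", "E"})

    def test_unknown_taxon_rejected(self, tree):
        with pytest.raises(ValueError, match="not in tree"):
            phylo.is_monophyletic(tree, {"A", "Z"})

    def test_planted_clade_recovered_from_sequences(self):
        rng = np.random.default_rng(21)
        ancestor = sim.random_protein(200, rng)
        members = {f"in{i}": sim.evolve_protein(ancestor, 0.04, rng)
                   for i in range(5)}
        members.update({f"out{i}": sim.evolve_protein(ancestor, 0.4, rng)
                        for i in range(2)})
        tree = phylo.neighbor_joining(phylo.marker_distance_matrix(members))
        assert phylo.is_monophyletic(tree, {f"in{i}" for i in range(5)})
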