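import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popscan.genotype_io import MISSING, DataError
from popscan.phylo import (
    DistanceMatrix,
    neighbor_joining,
    p_distance,
    root_with_outgroup,
)
from popscan.reference import ref_p_distance

from conftest import make_gm


def _dm(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(labels=list(labels), d=d, defined=np.ones_like(d, dtype=bool))


WORKED_4TAXON = np.array(
    [
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ],
    dtype=float,
)


def _tree_from_edges(adj, leaves):
    """Leaf-to-leaf path lengths from an adjacency dict (oracle helper)."""
    import heapq

    out = {}
    for a in leaves:
        dist = {a: 0.0}
        heap = [(0.0, a)]
        while heap:
            dcur, node = heapq.heappop(heap)
            for nbr, ln in adj[node]:
                nd = dcur + ln
                if nbr not in dist or nd < dist[nbr]:
                    dist[nbr] = nd
                    heapq.heappush(heap, (nd, nbr))
        for b in leaves:
            if a < b:
                out[(a, b)] = dist[b]
    return out


class TestPDistance:
    def test_identical_samples_zero(self):
        dos = np.array([[1, 1], [2, 2], [0, 0]], dtype=np.int8)
        dm = p_distance(make_gm(dos))
        assert dm.d[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        dos = np.array([[0, 2], [2, 0]], dtype=np.int8)
        dm = p_distance(make_gm(dos))
        assert dm.d[0, 1] == 1.0

    def test_het_half(self):
        dos = np.array([[0, 1]], dtype=np.int8)
        dm = p_distance(make_gm(dos))
        assert dm.d[0, 1] == 0.5

    def test_missing_pair_flagged(self):
        dos = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        dm = p_distance(make_gm(dos))
        assert np.isnan(dm.d[0, 1])
        assert not dm.defined[0, 1]

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(-1, 3, size=(30, 6)).astype(np.int8)
        dm = p_distance(make_gm(dos))
        np.testing.assert_allclose(dm.d, dm.d.T, equal_nan=True)
        assert np.all(np.diag(dm.d) == 0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_brute_force_allele_pairing_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(1, 40))
        dos = rng.integers(-1, 3, size=(n_sites, 4)).astype(np.int8)
        dm = p_distance(make_gm(dos))
        for i in range(4):
            for j in range(i + 1, 4):
                ref = ref_p_distance(dos[:, i], dos[:, j])
                if np.isnan(ref):
                    assert np.isnan(dm.d[i, j])
                else:
                    assert dm.d[i, j] == pytest.approx(ref, abs=1e-12)
                    assert 0.0 <= dm.d[i, j] <= 1.0


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        tree = neighbor_joining(_dm("ABCD", WORKED_4TAXON))
        dists = tree.leaf_distances()
        for (a, b), expected in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert dists[(a, b)] == pytest.approx(expected, abs=1e-9)
        # AB|CD topology: newick groups A with B
        nwk = tree.to_newick()
        assert "(A:1,B:2)" in nwk

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(_dm("ABC", d))
        dists = tree.leaf_distances()
        assert dists[("A", "B")] == pytest.approx(4)
        assert dists[("A", "C")] == pytest.approx(6)
        assert dists[("B", "C")] == pytest.approx(8)

    def test_five_taxon_additive_recovery(self):
        # caterpillar tree ((A:2,B:3):1,C:4):2,(D:2,E:1) with internal edges
        adj = {
            "u": [("A", 2.0), ("B", 3.0), ("v", 1.5)],
            "v": [("u", 1.5), ("C", 4.0), ("w", 2.5)],
            "w": [("v", 2.5), ("D", 2.0), ("E", 1.0)],
            "A": [("u", 2.0)], "B": [("u", 3.0)], "C": [("v", 4.0)],
            "D": [("w", 2.0)], "E": [("w", 1.0)],
        }
        leaves = ["A", "B", "C", "D", "E"]
        want = _tree_from_edges(adj, leaves)
        D = np.zeros((5, 5))
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i < j:
                    D[i, j] = D[j, i] = want[(a, b)]
        tree = neighbor_joining(_dm(leaves, D))
        got = tree.leaf_distances()
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(DataError):
            neighbor_joining(_dm("AB", np.array([[0, 1], [1, 0]], float)))

    def test_undefined_pairs_rejected(self):
        dm = _dm("ABC", np.zeros((3, 3)))
        dm.defined[0, 1] = dm.defined[1, 0] = False
        with pytest.raises(DataError):
            neighbor_joining(dm)

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(_dm("ABCD", d)).to_newick()
        t2 = neighbor_joining(_dm("ABCD", d)).to_newick()
        assert t1 == t2

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        labels = ["A", "B", "C", "D", "E"]
        # random additive tree distances via random positive branch lengths
        adj = {
            "u": [("A", 1.0), ("B", 2.2), ("v", 0.7)],
            "v": [("u", 0.7), ("C", 3.1), ("w", 1.9)],
            "w": [("v", 1.9), ("D", 0.4), ("E", 2.8)],
            "A": [("u", 1.0)], "B": [("u", 2.2)], "C": [("v", 3.1)],
            "D": [("w", 0.4)], "E": [("w", 2.8)],
        }
        want = _tree_from_edges(adj, labels)
        D = np.zeros((5, 5))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    D[i, j] = D[j, i] = want[(a, b)]
        perm = rng.permutation(5)
        plabels = [labels[i] for i in perm]
        got = neighbor_joining(_dm(plabels, D[np.ix_(perm, perm)])).leaf_distances()
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-9)

    def test_matches_scikit_bio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        rng = np.random.default_rng(7)
        n = 6
        pts = rng.random((n, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(_dm(labels, D)).leaf_distances()
        sk_tree = nj(SkbioDM(D, ids=labels))
        for i in range(n):
            for j in range(i + 1, n):
                sk_d = sk_tree.find(labels[i]).distance(sk_tree.find(labels[j]))
                key = (labels[i], labels[j])
                assert mine[key] == pytest.approx(sk_d, abs=1e-6)


class TestRooting:
    def test_root_on_outgroup_preserves_structure(self):
        tree = neighbor_joining(_dm("ABCD", WORKED_4TAXON))
        rooted = root_with_outgroup(tree, "D")
        nwk = rooted.to_newick()
        assert nwk.startswith("(D:2")
        assert "(A:1,B:2)" in nwk

    def test_idempotent(self):
        tree = neighbor_joining(_dm("ABCD", WORKED_4TAXON))
        r1 = root_with_outgroup(tree, "D")
        r2 = root_with_outgroup(r1, "D")
        assert r1.to_newick() == r2.to_newick()

    def test_path_lengths_preserved(self):
        tree = neighbor_joining(_dm("ABCD", WORKED_4TAXON))
        before = tree.leaf_distances()
        after = root_with_outgroup(tree, "C").leaf_distances()
        for key, val in before.items():
            assert after[key] == pytest.approx(val, abs=1e-9)

    def test_missing_outgroup_rejected(self):
        tree = neighbor_joining(_dm("ABCD", WORKED_4TAXON))
        with pytest.raises(DataError):
            root_with_outgroup(tree, "ZZZ")


def test_negative_branch_clamped_flagged():
    # distances violating additivity can force a negative NJ branch
    d = np.array(
        [
            [0.0, 0.1, 0.6, 0.6],
            [0.1, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.05],
            [0.6, 0.6, 0.05, 0.0],
        ]
    )
    tree = neighbor_joining(_dm("ABCD", d))
    nwk = tree.to_newick()
    assert ":-" not in nwk  # no negative lengths serialized
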