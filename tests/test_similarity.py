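import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.optimize import linprog
from scipy.spatial.distance import squareform

from epsim.gwdist import DistanceHistogram
from epsim.similarity import (Dendrogram, PairwiseDistanceMatrix,
                              build_distance_matrix, cut_clusters,
                              emd_histograms, to_newick, upgma)


def hist(counts, edges=None, labels=("A", "B")):
    counts = np.asarray(counts)
    n = int(counts.sum())
    edges = np.arange(len(counts) + 1.0) if edges is None else np.asarray(edges)
    # synthesize samples at bin centers so the invariants hold
    centers = 0.5 * (edges[:-1] + edges[1:])
    samples = np.repeat(centers, counts)
    return DistanceHistogram(pair_labels=tuple(labels), samples=samples,
                             n_points=10, n_reps=n, bin_edges=edges,
                             counts=counts)


def emd_lp_oracle(pa, pb, centers):
    """Transportation LP optimum between two histograms on shared centers."""
    n = len(centers)
    cost = np.abs(centers[:, None] - centers[None, :]).ravel()
    A_eq, b_eq = [], []
    for i in range(n):
        row = np.zeros((n, n)); row[i, :] = 1
        A_eq.append(row.ravel()); b_eq.append(pa[i])
    for j in range(n):
        col = np.zeros((n, n)); col[:, j] = 1
        A_eq.append(col.ravel()); b_eq.append(pb[j])
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun


class TestEMD:
    def test_identical_histograms(self):
        h = hist([5, 3, 2])
        assert emd_histograms(h, h) == 0.0

    def test_unit_translocation(self):
        a = hist([10, 0])
        b = hist([0, 10])
        assert emd_histograms(a, b) == pytest.approx(1.0)

    def test_matches_transportation_lp(self, rng):
        for _ in range(10):
            k = int(rng.integers(4, 17))
            ca = rng.integers(0, 20, k); ca[0] += 1
            cb = rng.integers(0, 20, k); cb[0] += 1
            edges = np.arange(k + 1.0) * rng.uniform(0.5, 2.0)
            a, b = hist(ca, edges), hist(cb, edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            expected = emd_lp_oracle(ca / ca.sum(), cb / cb.sum(), centers)
            assert emd_histograms(a, b) == pytest.approx(expected, abs=1e-9)

    def test_mismatched_edges_rejected(self):
        a = hist([1, 2, 3])
        b = hist([1, 2, 3], edges=np.array([0.0, 2, 4, 6]))
        with pytest.raises(ValueError, match="mismatched"):
            emd_histograms(a, b)


class TestBuildMatrix:
    def test_identical_histograms_give_zero_matrix(self):
        hists = [hist([5, 5], labels=l) for l in (("A", "A"), ("A", "B"), ("B", "B"))]
        M = build_distance_matrix(hists)
        assert M.labels == ["A", "B"]
        assert np.all(M.M == 0.0)

    def test_three_labels_mirrored(self):
        pairs = [("A", "A"), ("B", "B"), ("C", "C"),
                 ("A", "B"), ("A", "C"), ("B", "C")]
        rng = np.random.default_rng(0)
        hists = [hist(rng.integers(1, 10, 8), labels=p) for p in pairs]
        M = build_distance_matrix(hists)
        assert np.allclose(M.M, M.M.T)
        assert np.all(np.diag(M.M) == 0)

    def test_missing_pair_rejected(self):
        hists = [hist([1, 2], labels=("A", "B")), hist([1, 2], labels=("C", "D"))]
        with pytest.raises(ValueError, match="missing histogram"):
            build_distance_matrix(hists)

    def test_label_permutation_consistency(self):
        rng = np.random.default_rng(1)
        pairs = [("A", "A"), ("B", "B"), ("C", "C"),
                 ("A", "B"), ("A", "C"), ("B", "C")]
        hists = {p: hist(rng.integers(1, 10, 8), labels=p) for p in pairs}
        M1 = build_distance_matrix(list(hists.values()))
        order2 = [("C", "C"), ("B", "B"), ("A", "A"),
                  ("B", "C"), ("A", "C"), ("A", "B")]
        M2 = build_distance_matrix([hists[p] for p in order2])
        perm = [M2.labels.index(l) for l in M1.labels]
        assert np.allclose(M1.M, M2.M[np.ix_(perm, perm)])


def matrix(labels, entries):
    n = len(labels)
    M = np.zeros((n, n))
    for (i, j), v in entries.items():
        M[i, j] = M[j, i] = v
    return PairwiseDistanceMatrix(labels=list(labels), M=M)


class TestUPGMA:
    def test_three_leaf_worked_example(self):
        M = matrix("ABC", {(0, 1): 2.0, (0, 2): 4.0, (1, 2): 6.0})
        tree = upgma(M)
        (a1, b1, d1, s1), (a2, b2, d2, s2) = tree.merges
        assert (a1, b1, d1, s1) == (0, 1, 2.0, 2)
        assert d2 == pytest.approx(5.0)  # mean(4, 6)
        assert s2 == 3

    def test_all_equal_distances(self):
        M = matrix("ABCD", {(i, j): 3.0 for i in range(4) for j in range(i + 1, 4)})
        tree = upgma(M)
        assert all(m[2] == pytest.approx(3.0) for m in tree.merges)

    def test_matches_scipy_average_linkage(self, rng):
        for _ in range(50):
            n = 6
            D = squareform(rng.uniform(1, 10, n * (n - 1) // 2))
            mine = upgma(PairwiseDistanceMatrix(labels=list("abcdef"), M=D))
            ref = linkage(squareform(D), method="average")
            assert np.allclose(mine.to_linkage()[:, 2], ref[:, 2], atol=1e-9)

    def test_matches_bruteforce_average_linkage(self, rng):
        # independent O(n^3) reference recomputing all cross-pair means
        def brute(D):
            n = len(D)
            clusters = [[i] for i in range(n)]
            heights = []
            while len(clusters) > 1:
                best = None
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        d = np.mean([D[p, q] for p in clusters[i]
                                     for q in clusters[j]])
                        if best is None or d < best[0]:
                            best = (d, i, j)
                d, i, j = best
                heights.append(d)
                clusters[i] = clusters[i] + clusters[j]
                del clusters[j]
            return heights

        for _ in range(10):
            n = 6
            D = squareform(rng.uniform(1, 10, n * (n - 1) // 2))
            mine = upgma(PairwiseDistanceMatrix(labels=list("abcdef"), M=D))
            assert np.allclose(mine.to_linkage()[:, 2], brute(D), atol=1e-9)

    def test_merge_heights_non_decreasing(self, rng):
        for _ in range(20):
            D = squareform(rng.uniform(1, 10, 28))
            h = upgma(PairwiseDistanceMatrix(labels=list("abcdefgh"), M=D)) \
                .to_linkage()[:, 2]
            assert np.all(np.diff(h) >= -1e-12)

    def test_shift_equivariance(self, rng):
        D = squareform(rng.uniform(1, 10, 15))
        M1 = PairwiseDistanceMatrix(labels=list("abcdef"), M=D)
        c = 2.5
        D2 = D + c
        np.fill_diagonal(D2, 0.0)
        M2 = PairwiseDistanceMatrix(labels=list("abcdef"), M=D2)
        h1 = upgma(M1).to_linkage()[:, 2]
        h2 = upgma(M2).to_linkage()[:, 2]
        assert np.allclose(h2, h1 + c, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            PairwiseDistanceMatrix(labels=["a", "b"],
                                   M=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNewick:
    def test_two_leaf_convention(self):
        d = Dendrogram(leaf_labels=["A", "B"], merges=[(0, 1, 2.0, 2)])
        assert to_newick(d) == "(A:1,B:1);"

    def test_three_leaf_convention(self):
        d = Dendrogram(leaf_labels=["A", "B", "C"],
                       merges=[(0, 1, 2.0, 2), (2, 3, 5.0, 3)])
        assert to_newick(d) == "((A:1,B:1):1.5,C:2.5);"

    def test_round_trip_topology(self):
        from io import StringIO
        from Bio import Phylo
        M = matrix("ABC", {(0, 1): 2.0, (0, 2): 4.0, (1, 2): 6.0})
        nwk = to_newick(upgma(M))
        tree = Phylo.read(StringIO(nwk), "newick")
        names = sorted(t.name for t in tree.get_terminals())
        assert names == ["A", "B", "C"]
        # A and B form the cherry
        a = next(t for t in tree.get_terminals() if t.name == "A")
        path = tree.get_path(a)
        cherry = path[-2] if len(path) >= 2 else tree.root
        assert sorted(t.name for t in cherry.get_terminals()) == ["A", "B"]

    def test_labels_with_spaces_are_quoted(self):
        d = Dendrogram(leaf_labels=["CITRX / Trxz", "B"], merges=[(0, 1, 2.0, 2)])
        assert to_newick(d) == "('CITRX / Trxz':1,B:1);"


class TestCutClusters:
    @pytest.fixture
    def worked_tree(self):
        return upgma(matrix("ABC", {(0, 1): 2.0, (0, 2): 4.0, (1, 2): 6.0}))

    def test_k_equals_n_gives_singletons(self, worked_tree):
        assert cut_clusters(worked_tree, 3) == {"A": 0, "B": 1, "C": 2}

    def test_k_one_gives_single_cluster(self, worked_tree):
        assert set(cut_clusters(worked_tree, 1).values()) == {0}

    def test_worked_example_k2(self, worked_tree):
        got = cut_clusters(worked_tree, 2)
        assert got["A"] == got["B"] != got["C"]

    def test_k_out_of_range(self, worked_tree):
        with pytest.raises(ValueError):
            cut_clusters(worked_tree, 0)
        with pytest.raises(ValueError):
            cut_clusters(worked_tree, 4)
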