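"""From pairwise histograms to a distance matrix, a UPGMA tree, and clusters.

The earth-mover's distance between two binned histograms on a shared
support turns the repeated-subsampling samples of every protein pair into a
single scalar; UPGMA (average linkage on the arithmetic mean of all
cross-pair distances) builds an ultrametric dendrogram from the resulting
matrix, exported as Newick with the standard half-distance height
convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .gwdist import DistanceHistogram

__all__ = [
    "PairwiseDistanceMatrix",
    "Dendrogram",
    "emd_histograms",
    "build_distance_matrix",
    "upgma",
    "to_newick",
    "cut_clusters",
]


@dataclass
class PairwiseDistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    M: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        n = len(self.labels)
        if M.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(M)):
            raise ValueError("distances must be finite")
        if not np.allclose(M, M.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(M), 0):
            raise ValueError("diagonal must be zero")
        if np.any(M < 0):
            raise ValueError("distances must be non-negative")
        self.M = M

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.M):
                fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


@dataclass
class Dendrogram:
    """UPGMA merge history.

    ``merges[i] = (child_a, child_b, distance, size)`` where children index
    leaves as 0..n-1 and earlier merges as n+i (the scipy linkage
    convention); merge distances are non-decreasing.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self):
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        heights = [m[2] for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("UPGMA merge heights must be non-decreasing")

    def to_linkage(self) -> np.ndarray:
        """The merge list as a scipy-style linkage array."""
        return np.array([[a, b, d, s] for a, b, d, s in self.merges], dtype=float)


def emd_histograms(hist_a: DistanceHistogram, hist_b: DistanceHistogram) -> float:
    """Earth-mover's (Wasserstein-1) distance between two binned histograms.

    Counts are normalized to mass 1, so the number of repetitions cancels;
    on shared equal-width edges W1 = Σ_k |CDF_A(k) − CDF_B(k)|·bin_width.
    Histograms binned on different edge sets raise ValueError.
    """
    if hist_a.bin_edges is None or hist_b.bin_edges is None:
        raise ValueError("histograms must be binned first (see bin_samples)")
    if (len(hist_a.bin_edges) != len(hist_b.bin_edges)
            or not np.allclose(hist_a.bin_edges, hist_b.bin_edges)):
        raise ValueError("histograms have mismatched bin edges")
    edges = hist_a.bin_edges
    widths = np.diff(edges)
    pa = hist_a.counts / hist_a.counts.sum()
    pb = hist_b.counts / hist_b.counts.sum()
    cdf_gap = np.abs(np.cumsum(pa) - np.cumsum(pb))
    return float(np.sum(cdf_gap * widths))


def _emd_to_zero(h: DistanceHistogram) -> float:
    """W1 distance of a binned histogram to the point mass at zero.

    For a non-negative variable this is its expectation, evaluated on bin
    centers.
    """
    if h.bin_edges is None:
        raise ValueError("histogram must be binned first (see bin_samples)")
    centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
    p = h.counts / h.counts.sum()
    return float(np.sum(p * centers))


def build_distance_matrix(histograms: list[DistanceHistogram]) -> PairwiseDistanceMatrix:
    """Assemble the pairwise protein distance matrix from EMDs of histograms.

    Expects one histogram per unordered pair of labels (missing pairs
    raise); the diagonal is forced to zero.  When self-comparison
    histograms (pair (i, i)) are supplied as well, the entry for pair
    (i, j) is the subsampling-noise-corrected
    ½·[W1(h_ij, h_ii) + W1(h_ij, h_jj)], which vanishes when the pair
    histogram is indistinguishable from the self-comparison baselines;
    without self-pairs it falls back to W1(h_ij, δ0), the mean of the
    binned pair histogram.
    """
    labels: list[str] = []
    for h in histograms:
        for lab in h.pair_labels:
            if lab not in labels:
                labels.append(lab)
    index = {lab: i for i, lab in enumerate(labels)}
    by_pair: dict[tuple[int, int], DistanceHistogram] = {}
    for h in histograms:
        i, j = index[h.pair_labels[0]], index[h.pair_labels[1]]
        by_pair[(min(i, j), max(i, j))] = h
    n = len(labels)
    have_self = all((i, i) in by_pair for i in range(n))
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in by_pair:
                raise ValueError(f"missing histogram for pair ({labels[i]}, {labels[j]})")
            h_ij = by_pair[(i, j)]
            if have_self:
                M[i, j] = 0.5 * (emd_histograms(h_ij, by_pair[(i, i)])
                                 + emd_histograms(h_ij, by_pair[(j, j)]))
            else:
                M[i, j] = _emd_to_zero(h_ij)
            M[j, i] = M[i, j]
    return PairwiseDistanceMatrix(labels=labels, M=M)


def upgma(matrix: PairwiseDistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Repeatedly merges the closest pair of clusters; the distance between
    clusters is the arithmetic mean of all cross-pair leaf distances,
    maintained by the Lance-Williams size-weighted update.  Ties break on
    the smallest (i, j) pair of smallest-member leaf indices, so the result
    is deterministic across platforms.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 labels to cluster")
    D = matrix.M.copy().astype(float)
    # active cluster bookkeeping: scipy-style ids, sizes, smallest leaf index
    ids = list(range(n))
    sizes = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    pos = {i: i for i in range(n)}  # cluster id -> row of D
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        # find the closest active pair, ties by smallest (min_leaf_i, min_leaf_j)
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                ci, cj = active[ai], active[aj]
                d = D[pos[ci], pos[cj]]
                key_pair = tuple(sorted((min_leaf[ci], min_leaf[cj])))
                key = (d, key_pair)
                if best is None or key < best[0]:
                    best = (key, ci, cj)
        (_, _), ci, cj = best[0], best[1], best[2]
        d_merge = D[pos[ci], pos[cj]]
        si, sj = sizes[ci], sizes[cj]
        # Lance-Williams UPGMA update against every other active cluster
        for ck in active:
            if ck in (ci, cj):
                continue
            dik = D[pos[ci], pos[ck]]
            djk = D[pos[cj], pos[ck]]
            dnew = (si * dik + sj * djk) / (si + sj)
            D[pos[ci], pos[ck]] = D[pos[ck], pos[ci]] = dnew
        a, b = sorted((ci, cj))
        merges.append((a, b, float(d_merge), si + sj))
        # new cluster reuses ci's row
        sizes[next_id] = si + sj
        min_leaf[next_id] = min(min_leaf[ci], min_leaf[cj])
        pos[next_id] = pos[ci]
        active.remove(ci)
        active.remove(cj)
        active.append(next_id)
        next_id += 1
    return Dendrogram(leaf_labels=list(matrix.labels), merges=merges)


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.+-]+$")


def _escape_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick serialization with ultrametric branch lengths.

    Node height = merge distance / 2 (the standard UPGMA display
    convention); a branch length is the parent height minus the child
    height; leaves sit at height 0.
    """
    n = len(dendrogram.leaf_labels)
    height = {i: 0.0 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    node: dict[int, str] = {}
    for i in range(n):
        node[i] = _escape_label(dendrogram.leaf_labels[i])
    for k, (a, b, d, _size) in enumerate(dendrogram.merges):
        h = d / 2.0
        # children ordered by earliest leaf, so sibling order is deterministic
        if min_leaf[b] < min_leaf[a]:
            a, b = b, a
        nid = n + k
        node[nid] = f"({node[a]}:{_fmt(h - height[a])},{node[b]}:{_fmt(h - height[b])})"
        height[nid] = h
        min_leaf[nid] = min(min_leaf[a], min_leaf[b])
    return node[n + len(dendrogram.merges) - 1] + ";"


def _fmt(x: float) -> str:
    s = f"{x:.10g}"
    return s


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Flat clusters from the dendrogram: drop the k−1 highest merges.

    Returns label → cluster id; ids are assigned deterministically in leaf
    order (the cluster containing the first leaf is 0, and so on).
    """
    n = len(dendrogram.leaf_labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # merges are non-decreasing in height, so the k-1 highest are the last ones
    for idx, (a, b, _d, _s) in enumerate(dendrogram.merges[: n - k]):
        nid = n + idx
        parent[find(a)] = nid
        parent[find(b)] = nid

    cluster_ids: dict[int, int] = {}
    out: dict[str, int] = {}
    for leaf_idx, label in enumerate(dendrogram.leaf_labels):
        root = find(leaf_idx)
        if root not in cluster_ids:
            cluster_ids[root] = len(cluster_ids)
        out[label] = cluster_ids[root]
    return out
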