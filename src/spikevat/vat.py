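"""Visual assessment of cluster tendency (VAT / iVAT) on dissimilarity data.

VAT reorders a dissimilarity matrix by the insertion order of Prim's
minimal-spanning-tree construction, started from an endpoint of the
globally largest dissimilarity.  Displayed as a grayscale image, possible
clusters appear as dark blocks along the diagonal.  iVAT sharpens those
blocks by replacing each reordered entry with the minimax path distance —
the largest edge weight on the unique MST path between the pair — via an
O(n^2) recursion over the insertion order.

The MST also carries the single-linkage hierarchy: cutting the k-1
largest MST edges (the "back pass") yields exactly the k-cluster
single-linkage flat partition, and the largest gap in the sorted edge
weights gives a heuristic cluster-count suggestion.

Any symmetric, nonnegative, zero-diagonal matrix is accepted; it need not
satisfy the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import LabeledWaveformSet
from .validity import CrispPartition, partition_from_labels

ArrayLike = Union[np.ndarray, "DissimilarityMatrix"]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """A symmetric nonnegative matrix with zero diagonal.

    The only admission requirements are D = D^T, d_ij >= 0 and d_ii = 0;
    metric structure is not assumed.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("dissimilarity matrix has non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("dissimilarity matrix entries must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class VatResult:
    """Output of the VAT reordering (and optionally the iVAT transform).

    Attributes
    ----------
    order : ndarray
        Permutation of 0..n-1: original object index per insertion step.
    mst_edges : tuple of (parent, child, weight)
        MST edges in insertion order (original 0-based indices); n-1 of
        them, spanning all objects.
    d_star : ndarray
        The reordered matrix D* = D[order][:, order].
    d_prime_star : ndarray, optional
        The iVAT (minimax-path) transform D'* of D*, in reordered
        coordinates; present after :func:`ivat_transform`.
    """

    order: np.ndarray
    mst_edges: tuple
    d_star: np.ndarray
    d_prime_star: Optional[np.ndarray] = None


def _as_values(d: ArrayLike) -> np.ndarray:
    if isinstance(d, DissimilarityMatrix):
        return d.values
    return DissimilarityMatrix(np.asarray(d, dtype=float)).values


def pairwise_euclidean(
    x: Union[np.ndarray, LabeledWaveformSet]
) -> DissimilarityMatrix:
    """Euclidean distance matrix of a waveform set (rows = objects)."""
    if isinstance(x, LabeledWaveformSet):
        x = x.waveforms
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("need an n x p matrix with n >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    if x.shape[0] == 1:
        return DissimilarityMatrix(np.zeros((1, 1)))
    return DissimilarityMatrix(squareform(pdist(x)))


def vat_reorder(d: ArrayLike) -> VatResult:
    """VAT reordering of a dissimilarity matrix.

    Starts at an endpoint of the globally largest dissimilarity (the
    smaller index of the first maximal entry in row-major scan), then
    grows Prim's MST by repeatedly inserting the unvisited object at
    minimum distance to the visited set (ties: smallest original index).
    The insertion sequence is the VAT order; D* is D conjugated by it.
    """
    dv = _as_values(d)
    n = dv.shape[0]
    if n < 2:
        raise ValueError("VAT needs at least 2 objects")

    # Start vertex: smaller index of the first row-major argmax of D.
    flat = int(np.argmax(dv))
    i0, j0 = divmod(flat, n)
    start = min(i0, j0)

    order = np.empty(n, dtype=int)
    order[0] = start
    visited = np.zeros(n, dtype=bool)
    visited[start] = True
    # best_dist[j]/best_from[j]: cheapest connection of unvisited j to the tree.
    best_dist = dv[start].copy()
    best_from = np.full(n, start)
    edges = []
    for r in range(1, n):
        masked = np.where(visited, np.inf, best_dist)
        nxt = int(np.argmin(masked))  # argmin takes the smallest index on ties
        edges.append((int(best_from[nxt]), nxt, float(dv[best_from[nxt], nxt])))
        order[r] = nxt
        visited[nxt] = True
        closer = dv[nxt] < best_dist
        best_dist = np.where(closer, dv[nxt], best_dist)
        best_from = np.where(closer, nxt, best_from)

    d_star = dv[np.ix_(order, order)]
    return VatResult(order=order, mst_edges=tuple(edges), d_star=d_star)


def ivat_transform(v: VatResult) -> VatResult:
    """iVAT transform: replace each D* entry by its MST minimax path distance.

    For the r-th inserted object with MST parent j (both in reordered
    coordinates): d'_rj = d*_rj and d'_rc = max(d*_rj, d'_jc) for every
    earlier-inserted c != j.  O(n^2) total; the result equals the
    max-edge-on-path distance through the MST for every pair.
    """
    if v.d_star is None or not v.mst_edges:
        raise ValueError("VatResult lacks the reordered matrix or MST")
    n = v.d_star.shape[0]
    pos = np.empty(n, dtype=int)  # original index -> insertion position
    pos[v.order] = np.arange(n)
    dp = np.zeros_like(v.d_star)
    for r in range(1, n):
        parent, child, w = v.mst_edges[r - 1]
        j = pos[parent]
        assert pos[child] == r
        dp[r, j] = dp[j, r] = w
        earlier = np.arange(r)
        earlier = earlier[earlier != j]
        vals = np.maximum(w, dp[j, earlier])
        dp[r, earlier] = vals
        dp[earlier, r] = vals
    return VatResult(
        order=v.order, mst_edges=v.mst_edges, d_star=v.d_star, d_prime_star=dp
    )


def single_linkage_partition(v: VatResult, k: int) -> CrispPartition:
    """Back pass: cut the k-1 largest MST edges and return the components.

    Equivalent to the k-cluster single-linkage flat clustering.  Ties in
    edge weight are broken by later insertion order (later-inserted equal
    edges are cut first).  Cluster ids follow first appearance in the
    original object order.
    """
    n = len(v.order)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    ranked = sorted(
        range(n - 1),
        key=lambda e: (v.mst_edges[e][2], e),
        reverse=True,
    )
    cut = set(ranked[: k - 1])
    # Union-find over the kept edges.
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for e, (a, b, _) in enumerate(v.mst_edges):
        if e not in cut:
            parent[find(a)] = find(b)
    roots = [find(i) for i in range(n)]
    return partition_from_labels(np.asarray(roots) + 1)


def estimate_cluster_count(v: VatResult, max_k: int) -> int:
    """Heuristic cluster-count suggestion from the MST edge-weight gap.

    The few largest MST edges typically join clusters while the rest join
    neighbors; the largest gap in the sorted weight sequence separates the
    two regimes.  Returns 1 + (number of edges above that gap), capped at
    ``max_k``.  With all edges equal (no gap) returns 1.  Heuristic only:
    never used by the other operations.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    w = np.sort([e[2] for e in v.mst_edges])
    if w.size < 2:
        return 1  # a single edge carries no gap evidence
    gaps = np.diff(w)
    if gaps.max() == 0:
        return 1
    cut = int(np.argmax(gaps))  # first occurrence on ties
    above = w.size - (cut + 1)
    return min(1 + above, max_k)


def render_ivat_image(d_prime: ArrayLike, path) -> np.ndarray:
    """Write a dissimilarity matrix as an 8-bit grayscale PNG.

    One pixel per entry; intensity = round(255 * d / max(D)), so zero
    distance is black and the maximum is white.  A constant-zero matrix
    renders all black.  Returns the pixel array that was written.
    """
    dv = _as_values(d_prime)
    top = dv.max()
    if top > 0:
        pixels = np.round(255.0 * dv / top).astype(np.uint8)
    else:
        pixels = np.zeros_like(dv, dtype=np.uint8)
    iio.imwrite(path, pixels)
    return pixels


def ivat(d: ArrayLike) -> VatResult:
    """Convenience: VAT reordering followed by the iVAT transform."""
    return ivat_transform(vat_reorder(d))
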