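"""Crisp partitions and cluster validity indices.

Implements the three indices used to score spike-sorting partitions:

* **Dunn's index (DI)** — min single-linkage inter-cluster distance over
  max cluster diameter.  Max-optimal; DI > 1 characterizes a compact and
  separated partition.
* **GDI33** — the generalized Dunn index pairing the average cross-pair
  distance (delta_3) with twice the mean distance to the cluster centroid
  (Delta_3).  More robust to outliers than DI.
* **Adjusted Rand index (ARI)** — chance-corrected pair-counting agreement
  between two crisp partitions; maximal at 1.

The internal representation of a crisp partition is a label vector with
cluster ids compacted to ``1..k``; the equivalent ``k x n`` binary
membership matrix is a derived view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

Metric = Callable[[np.ndarray, np.ndarray], np.ndarray]


def euclidean_metric(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between rows of ``a`` and rows of ``b``."""
    return cdist(np.atleast_2d(a), np.atleast_2d(b))


@dataclass(frozen=True)
class CrispPartition:
    """A hard k-partition of n objects, stored as a label vector.

    ``labels[j]`` is the cluster id (1..k) of object j.  Every object has
    exactly one label and every id in 1..k occurs at least once.  Use
    :func:`partition_from_labels` to build one from arbitrary integer
    labels; ids are compacted to 1..k in first-appearance order.
    """

    labels: np.ndarray
    k: int
    n: int

    def to_matrix(self) -> np.ndarray:
        """The equivalent k x n binary membership matrix U (rows: clusters)."""
        u = np.zeros((self.k, self.n), dtype=int)
        u[self.labels - 1, np.arange(self.n)] = 1
        return u

    @classmethod
    def from_matrix(cls, u: np.ndarray) -> "CrispPartition":
        """Rebuild a partition from a k x n binary membership matrix."""
        u = np.asarray(u)
        if u.ndim != 2 or not np.all(np.isin(u, (0, 1))):
            raise ValueError("U must be a binary k x n matrix")
        if not np.all(u.sum(axis=0) == 1):
            raise ValueError("every object must belong to exactly one cluster")
        if not np.all(u.sum(axis=1) > 0):
            raise ValueError("every cluster must be nonempty")
        return cls(labels=u.argmax(axis=0) + 1, k=u.shape[0], n=u.shape[1])

    def members(self, cluster_id: int) -> np.ndarray:
        """Row indices of the objects in cluster ``cluster_id`` (1-based id)."""
        return np.flatnonzero(self.labels == cluster_id)

    def sizes(self) -> np.ndarray:
        """Cluster sizes, indexed by cluster id - 1."""
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def partition_from_labels(labels: Sequence[int]) -> CrispPartition:
    """Build a crisp partition from an arbitrary integer label vector.

    Ids are compacted to 1..k preserving first-appearance order, so
    ``[2, 1]`` becomes ids ``[1, 2]``.  Round-trip through the binary
    membership matrix is lossless.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no objects: empty label vector")
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D vector")
    if not np.issubdtype(labels.dtype, np.integer):
        as_int = labels.astype(int)
        if not np.all(np.isfinite(labels)) or not np.all(as_int == labels):
            raise ValueError("labels must be finite integers")
        labels = as_int
    # np.unique returns first-occurrence indices; sorting them preserves
    # first-appearance order of the distinct ids.
    uniq, first = np.unique(labels, return_index=True)
    order = uniq[np.argsort(first)]
    remap = {int(old): new + 1 for new, old in enumerate(order)}
    compact = np.array([remap[int(v)] for v in labels], dtype=int)
    return CrispPartition(labels=compact, k=len(order), n=labels.size)


def _validate_members(x: np.ndarray, members: np.ndarray, name: str) -> np.ndarray:
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError(f"{name}: empty member set")
    return members


def cluster_diameter(
    x: np.ndarray, members: Sequence[int], metric: Metric = euclidean_metric
) -> float:
    """Diameter of a cluster: max distance between any two of its members.

    A singleton has diameter 0.
    """
    x = np.asarray(x, dtype=float)
    members = _validate_members(x, np.asarray(members), "cluster_diameter")
    if members.size == 1:
        return 0.0
    d = metric(x[members], x[members])
    return float(d.max())


def set_distance(
    x: np.ndarray,
    members_i: Sequence[int],
    members_j: Sequence[int],
    metric: Metric = euclidean_metric,
) -> float:
    """Single-linkage distance between two disjoint clusters.

    The minimum distance over all cross pairs (one point from each set).
    """
    x = np.asarray(x, dtype=float)
    mi = _validate_members(x, np.asarray(members_i), "set_distance")
    mj = _validate_members(x, np.asarray(members_j), "set_distance")
    if np.intersect1d(mi, mj).size:
        raise ValueError("set_distance: member sets overlap")
    return float(metric(x[mi], x[mj]).min())


def _check_partition_for_dunn(partition: CrispPartition) -> None:
    if partition.k < 2:
        raise ValueError("validity index requires k >= 2 clusters")


def dunn_index(
    x: np.ndarray, partition: CrispPartition, metric: Metric = euclidean_metric
) -> float:
    """Dunn's separation index of a crisp partition.

    DI = (min over cluster pairs of the single-linkage set distance) /
    (max over clusters of the diameter).  Raises if all clusters are
    singletons (zero denominator: the partition carries no notion of
    compactness).
    """
    x = np.asarray(x, dtype=float)
    _check_partition_for_dunn(partition)
    members = [partition.members(c) for c in range(1, partition.k + 1)]
    max_diam = max(cluster_diameter(x, m, metric) for m in members)
    if max_diam == 0.0:
        raise ValueError("degenerate partition: all clusters are singletons")
    min_sep = min(
        set_distance(x, members[i], members[j], metric)
        for i in range(partition.k)
        for j in range(i + 1, partition.k)
    )
    return min_sep / max_diam


def gdi33(
    x: np.ndarray, partition: CrispPartition, metric: Metric = euclidean_metric
) -> float:
    """Generalized Dunn index GDI33.

    Uses Delta_3(X_k) = 2 * mean distance of the members of X_k to their
    centroid, and delta_3(X_i, X_j) = mean over all cross-pair distances.
    GDI33 = min pairwise delta_3 / max Delta_3.  A singleton cluster has
    Delta_3 = 0; an all-singleton partition raises (zero denominator).
    """
    x = np.asarray(x, dtype=float)
    _check_partition_for_dunn(partition)
    members = [partition.members(c) for c in range(1, partition.k + 1)]
    deltas = []
    for m in members:
        centroid = x[m].mean(axis=0, keepdims=True)
        deltas.append(2.0 * float(metric(x[m], centroid).mean()))
    max_delta = max(deltas)
    if max_delta == 0.0:
        raise ValueError("degenerate partition: zero maximum Delta_3")
    min_sep = min(
        float(metric(x[members[i]], x[members[j]]).mean())
        for i in range(partition.k)
        for j in range(i + 1, partition.k)
    )
    return min_sep / max_delta


def pair_counts(u: CrispPartition, v: CrispPartition) -> tuple[int, int, int, int]:
    """Pair-confusion counts (a, b, c, e) between two crisp partitions.

    Over all n(n-1)/2 object pairs: ``a`` same cluster in both, ``b`` same
    in V only, ``c`` same in U only, ``e`` different in both.  Computed
    from the k x r contingency table rather than explicit pair loops.
    """
    if u.n != v.n:
        raise ValueError("partitions must label the same number of objects")
    contingency = np.zeros((u.k, v.k), dtype=np.int64)
    np.add.at(contingency, (u.labels - 1, v.labels - 1), 1)
    n = u.n
    total = n * (n - 1) // 2
    same_both = int((contingency * (contingency - 1) // 2).sum())
    row = contingency.sum(axis=1)
    col = contingency.sum(axis=0)
    same_u = int((row * (row - 1) // 2).sum())
    same_v = int((col * (col - 1) // 2).sum())
    a = same_both
    c = same_u - same_both
    b = same_v - same_both
    e = total - a - b - c
    return a, b, c, e


def adjusted_rand(u: CrispPartition, v: CrispPartition) -> float:
    """Adjusted Rand index between two crisp partitions.

    ARI = 2(ae - bc) / [(a+b)(e+b) + (a+c)(e+c)] with the pair counts of
    :func:`pair_counts`.  Symmetric, invariant to cluster-id renaming,
    bounded above by 1.  When the denominator is 0 (both partitions
    trivial) the convention is 1 for identical partitions, else 0.
    """
    a, b, c, e = pair_counts(u, v)
    denom = (a + b) * (e + b) + (a + c) * (e + c)
    if denom == 0:
        # Both partitions trivial; they are the same partition iff no pair
        # is split differently.
        return 1.0 if (b == 0 and c == 0) else 0.0
    return 2.0 * (a * e - b * c) / denom
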