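"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
validity indices are recomputed by explicit pair enumeration, and the
minimax path distance by relaxation over the *full* graph rather than
the MST recursion.
"""

from __future__ import annotations

import numpy as np
import pytest


# ---------------------------------------------------------------- oracles


def brute_force_ari(labels_u: np.ndarray, labels_v: np.ndarray) -> float:
    """ARI by explicit enumeration of all object pairs."""
    n = len(labels_u)
    a = b = c = e = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_u = labels_u[i] == labels_u[j]
            same_v = labels_v[i] == labels_v[j]
            if same_u and same_v:
                a += 1
            elif same_v:
                b += 1
            elif same_u:
                c += 1
            else:
                e += 1
    denom = (a + b) * (e + b) + (a + c) * (e + c)
    if denom == 0:
        return 1.0 if (b == 0 and c == 0) else 0.0
    return 2.0 * (a * e - b * c) / denom


def brute_force_dunn(x: np.ndarray, labels: np.ndarray) -> float:
    """Dunn's index by double loops over every point pair."""
    ids = sorted(set(labels.tolist()))
    diam = 0.0
    for cid in ids:
        pts = x[labels == cid]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                diam = max(diam, float(np.linalg.norm(pts[i] - pts[j])))
    sep = np.inf
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            pa = x[labels == ids[ai]]
            pb = x[labels == ids[bi]]
            for u in pa:
                for v in pb:
                    sep = min(sep, float(np.linalg.norm(u - v)))
    return sep / diam


def brute_force_gdi33(x: np.ndarray, labels: np.ndarray) -> float:
    """GDI33 by explicit enumeration."""
    ids = sorted(set(labels.tolist()))
    deltas = []
    for cid in ids:
        pts = x[labels == cid]
        centroid = pts.mean(axis=0)
        deltas.append(2.0 * np.mean([np.linalg.norm(p - centroid) for p in pts]))
    sep = np.inf
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            pa = x[labels == ids[ai]]
            pb = x[labels == ids[bi]]
            cross = [np.linalg.norm(u - v) for u in pa for v in pb]
            sep = min(sep, float(np.mean(cross)))
    return sep / max(deltas)


def brute_force_minimax(d: np.ndarray) -> np.ndarray:
    """All-pairs minimax path distance over the full graph.

    Floyd-Warshall-style relaxation with (max, min) in place of (+, min);
    independent of any MST.
    """
    m = d.copy()
    n = m.shape[0]
    for k in range(n):
        m = np.minimum(m, np.maximum(m[:, k][:, None], m[k, :][None, :]))
    np.fill_diagonal(m, 0.0)
    return m


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric nonnegative zero-diagonal matrix."""
    a = rng.uniform(0.1, 10.0, size=(n, n))
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def random_labeled_points(
    rng: np.random.Generator, n: int, k: int, dim: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Random points with a random partition guaranteeing k nonempty clusters."""
    x = rng.normal(size=(n, dim))
    labels = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, size=n - k)])
    rng.shuffle(labels)
    return x, labels


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def gapped_line() -> np.ndarray:
    """The canonical 1-D set {0, 0.1, 5, 5.1}: two tight pairs, one gap."""
    return np.array([[0.0], [0.1], [5.0], [5.1]])


@pytest.fixture(scope="session")
def separated_mixture():
    """A well-separated 3-unit synthetic mixture (low noise, truth DI > 1)."""
    import spikevat as sv

    templates = sv.make_templates(3, 48, 24000.0, seed=11, max_correlation=0.9)
    spec = sv.MixtureSpec(
        unit_templates=templates,
        spikes_per_unit=[40, 40, 40],
        amplitude_model=sv.AmplitudeModel(sd=0.02, lo=1.05, hi=1.15),
        noise_sd=0.01,
        seed=11,
    )
    return sv.assemble_mixture(spec)
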