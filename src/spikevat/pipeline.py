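"""Evaluation pipeline: k-means with replicate selection, validity scoring,
and aggregation by true cluster count.

For each labeled mixture, k-means is run with k set to the number of
ground-truth subsets, in the upspace (raw waveforms) and in each requested
2-D representation.  Five replicates with fresh random initializations
are run per space and the replicate with the lowest within-cluster sum of
point-to-centroid distances is kept.  Each kept partition is scored with
the adjusted Rand index against the ground truth; the ground-truth
partition itself is scored with Dunn's index and GDI33 in the upspace.
Records aggregate to a mean +/- SD table per true cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import LabeledWaveformSet
from .features import embed
from .validity import (
    CrispPartition,
    adjusted_rand,
    dunn_index,
    gdi33,
    partition_from_labels,
)

STOCHASTIC_SPACES = {"tsne", "sammon"}


@dataclass(frozen=True)
class CandidateRange:
    """Inclusive range [c_min, c_max] of candidate cluster counts."""

    c_min: int
    c_max: int

    def __post_init__(self) -> None:
        if not 2 <= self.c_min <= self.c_max:
            raise ValueError("need 2 <= c_min <= c_max")

    def __iter__(self):
        return iter(range(self.c_min, self.c_max + 1))


@dataclass(frozen=True)
class KMeansRun:
    """Best-of-replicates k-means outcome."""

    partition: CrispPartition
    objective: float                 # within-cluster sum of distances, best run
    replicate_objectives: tuple      # one per replicate, same selection rule
    inertia: float                   # sklearn squared-error objective, best run


def _within_cluster_distance_sum(
    data: np.ndarray, labels: np.ndarray, centers: np.ndarray, squared: bool
) -> float:
    d = np.linalg.norm(data - centers[labels], axis=1)
    return float((d**2).sum() if squared else d.sum())


def kmeans_best_of(
    data: np.ndarray,
    k: int,
    replicates: int = 5,
    seed: int = 0,
    squared_selection: bool = False,
) -> KMeansRun:
    """k-means from ``replicates`` random initializations; keep the best run.

    The k-means objective itself is the standard squared-error criterion;
    replicate selection uses the within-cluster sum of point-to-centroid
    *distances* (unsquared) by default, switchable to squared sums with
    ``squared_selection``.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rep_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    best = None
    objectives = []
    for rs in rep_seeds:
        km = KMeans(n_clusters=k, n_init=1, init="random", random_state=int(rs))
        labels = km.fit_predict(data)
        obj = _within_cluster_distance_sum(
            data, labels, km.cluster_centers_, squared_selection
        )
        objectives.append(obj)
        if best is None or obj < best[0]:
            best = (obj, labels, float(km.inertia_))
    obj, labels, inertia = best
    return KMeansRun(
        partition=partition_from_labels(labels + 1),
        objective=obj,
        replicate_objectives=tuple(objectives),
        inertia=inertia,
    )


@dataclass
class EvaluationRecord:
    """Per-mixture evaluation: ground-truth validity + per-space ARI."""

    mixture_id: str
    k_true: int
    n: int
    ari: dict                      # space tag -> ARI (or None with a reason)
    dunn: Optional[float]
    gdi33: Optional[float]
    missing: dict = field(default_factory=dict)  # index/space -> reason
    seed: int = 0


def evaluate_mixture(
    mix: LabeledWaveformSet,
    spaces: Sequence[str] = ("pca", "pve", "wavelet", "tsne", "sammon"),
    replicates: int = 5,
    seed: int = 0,
    mixture_id: str = "",
    embed_kwargs: Optional[dict] = None,
) -> EvaluationRecord:
    """Score one labeled mixture in the upspace and each requested downspace.

    k is set to the number of ground-truth subsets.  Ground-truth DI and
    GDI33 are computed on the upspace; a degenerate denominator is
    recorded as missing with its reason rather than aborting.
    """
    if mix.labels is None:
        raise ValueError("evaluate_mixture needs a labeled mixture")
    truth = partition_from_labels(mix.labels)
    k = truth.k
    if k < 2:
        raise ValueError("mixture must contain at least 2 labeled subsets")
    embed_kwargs = dict(embed_kwargs or {})

    record = EvaluationRecord(
        mixture_id=mixture_id, k_true=k, n=mix.n, ari={}, dunn=None, gdi33=None,
        seed=seed,
    )
    try:
        record.dunn = dunn_index(mix.waveforms, truth)
    except ValueError as err:
        record.missing["dunn"] = str(err)
    try:
        record.gdi33 = gdi33(mix.waveforms, truth)
    except ValueError as err:
        record.missing["gdi33"] = str(err)

    child = np.random.SeedSequence(seed).generate_state(len(spaces) + 1) % (2**31)
    run = kmeans_best_of(mix.waveforms, k, replicates, seed=int(child[0]))
    record.ari["upspace"] = adjusted_rand(run.partition, truth)
    for i, space in enumerate(spaces):
        kwargs = dict(embed_kwargs.get(space, {}))
        if space in STOCHASTIC_SPACES:
            kwargs.setdefault("seed", int(child[i + 1]))
        emb = embed(mix, space, **kwargs)
        run = kmeans_best_of(emb.coords, k, replicates, seed=int(child[i + 1]))
        record.ari[space] = adjusted_rand(run.partition, truth)
    return record


def validity_over_combinations(
    subset_waveforms: Sequence[np.ndarray],
    k_values: Sequence[int],
    max_combinations: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ground-truth DI and GDI33 over subset-combination mixtures.

    Mirrors the combination design for labeled mixtures: from a fixed pool
    of per-unit waveform subsets, every k-element combination defines one
    mixture whose ground-truth partition is the subset membership.  Both
    indices factor into per-subset diameters/spreads and pairwise subset
    separations, so they are precomputed once and each combination is a
    table lookup.  ``max_combinations`` caps the per-k sample (random
    without replacement, seeded); by default all combinations are used,
    in which case the mean DI is non-increasing in k by construction
    (every larger combination contains smaller ones).
    """
    from itertools import combinations

    from scipy.spatial.distance import cdist

    m = len(subset_waveforms)
    diam = np.zeros(m)
    spread = np.zeros(m)  # Delta_3: twice the mean distance to centroid
    for i, w in enumerate(subset_waveforms):
        d = cdist(w, w)
        diam[i] = d.max()
        spread[i] = 2.0 * cdist(w, w.mean(axis=0, keepdims=True)).mean()
    setd = np.zeros((m, m))
    avgd = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            cross = cdist(subset_waveforms[i], subset_waveforms[j])
            setd[i, j] = setd[j, i] = cross.min()
            avgd[i, j] = avgd[j, i] = cross.mean()

    rng = np.random.default_rng(seed)
    rows = []
    for k in k_values:
        combos = list(combinations(range(m), k))
        if max_combinations is not None and len(combos) > max_combinations:
            pick = rng.choice(len(combos), size=max_combinations, replace=False)
            combos = [combos[i] for i in pick]
        di_vals, gdi_vals = [], []
        for combo in combos:
            pairs = [(a, b) for ai, a in enumerate(combo) for b in combo[ai + 1 :]]
            di_vals.append(
                min(setd[a, b] for a, b in pairs) / max(diam[c] for c in combo)
            )
            gdi_vals.append(
                min(avgd[a, b] for a, b in pairs) / max(spread[c] for c in combo)
            )
        rows.append(
            {
                "k_true": k,
                "n_mixtures": len(combos),
                "dunn_mean": float(np.mean(di_vals)),
                "dunn_std": float(np.std(di_vals, ddof=1)) if len(di_vals) > 1 else 0.0,
                "gdi33_mean": float(np.mean(gdi_vals)),
                "gdi33_std": float(np.std(gdi_vals, ddof=1)) if len(gdi_vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def aggregate_by_k(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Mean and SD of DI, GDI33 and per-space ARI, grouped by true k.

    Rows ascend in k; SD is the population-style pandas default (ddof=1,
    reported as 0 for singleton groups).
    """
    if not records:
        raise ValueError("no records to aggregate")
    rows = []
    for r in records:
        row = {"k_true": r.k_true, "dunn": r.dunn, "gdi33": r.gdi33}
        for space, value in r.ari.items():
            row[f"ari_{space}"] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    value_cols = [c for c in df.columns if c != "k_true"]
    agg = df.groupby("k_true")[value_cols].agg(["mean", "std"]).sort_index()
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    std_cols = [c for c in agg.columns if c.endswith("_std")]
    agg[std_cols] = agg[std_cols].fillna(0.0)
    return agg.reset_index()
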