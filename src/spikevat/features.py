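"""Two-dimensional representations of spike-waveform sets.

Five downspace projections are provided for pre-clustering visual
assessment and clustering:

* ``pca`` — projection onto the two leading eigenvectors of the sample
  covariance matrix.
* ``pve`` — the two physically meaningful waveform features: peak-to-valley
  time and energy (sum of squared samples).
* ``wavelet`` — a multi-level Haar decomposition per waveform, keeping the
  two coefficients whose distributions across the set deviate most from
  normality (Kolmogorov-Smirnov distance to a fitted normal), following
  the Waveclus lineage of wavelet feature selection.
* ``tsne`` — t-distributed stochastic neighbor embedding (delegated to
  scikit-learn's Barnes-Hut implementation).
* ``sammon`` — Sammon's nonlinear mapping, minimizing the
  inverse-distance-weighted stress by gradient descent from a PCA start.

All projections preserve row order and count.  ``pca``/``pve``/``wavelet``
are deterministic; ``tsne``/``sammon`` are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pywt
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .data import LabeledWaveformSet


@dataclass(frozen=True)
class Embedding2D:
    """An n x 2 downspace representation of a waveform set."""

    coords: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite embedding coordinates")
        object.__setattr__(self, "coords", c)


def _waveform_matrix(x: Union[np.ndarray, LabeledWaveformSet]) -> np.ndarray:
    if isinstance(x, LabeledWaveformSet):
        return x.waveforms
    return np.asarray(x, dtype=float)


def project_pca2(x: Union[np.ndarray, LabeledWaveformSet]) -> Embedding2D:
    """Project mean-centered waveforms onto the two leading covariance
    eigenvectors.

    The sign of each axis is fixed so that its largest-magnitude loading
    is positive.  ``params`` records the captured variance (lambda_1 +
    lambda_2) and both eigenvalues.
    """
    w = _waveform_matrix(x)
    n, p = w.shape
    if n < 3 or p < 2:
        raise ValueError("PCA projection needs n >= 3 and p >= 2")
    centered = w - w.mean(axis=0)
    if not np.any(centered):
        raise ValueError("rank-0 data: all waveforms identical")
    cov = np.cov(centered, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    idx = np.argsort(evals)[::-1][:2]
    lam = evals[idx]
    vecs = evecs[:, idx]
    for c in range(2):
        top = np.argmax(np.abs(vecs[:, c]))
        if vecs[top, c] < 0:
            vecs[:, c] = -vecs[:, c]
    coords = centered @ vecs
    return Embedding2D(
        coords,
        "pca",
        {"eigenvalues": lam.tolist(), "captured_variance": float(lam.sum())},
    )


def features_pv_e(
    x: Union[np.ndarray, LabeledWaveformSet],
    sampling_rate: Optional[float] = None,
    pv_amplitude: bool = False,
) -> Embedding2D:
    """Peak-to-valley and energy features (PV-E).

    PV is the absolute time between the waveform maximum and minimum in
    seconds (first index on flat ties, so a constant waveform has PV 0);
    set ``pv_amplitude`` for the max-minus-min amplitude variant instead.
    E is the energy: the raw sum of squared samples (amplitude^2 units,
    no sample-interval scaling).
    """
    w = _waveform_matrix(x)
    if w.shape[1] < 2:
        raise ValueError("waveforms need p >= 2 samples")
    if sampling_rate is None:
        if isinstance(x, LabeledWaveformSet):
            sampling_rate = x.sampling_rate
        elif not pv_amplitude:
            raise ValueError("sampling_rate required for peak-to-valley time")
    if pv_amplitude:
        pv = w.max(axis=1) - w.min(axis=1)
    else:
        pv = np.abs(w.argmax(axis=1) - w.argmin(axis=1)) / float(sampling_rate)
    energy = (w**2).sum(axis=1)
    return Embedding2D(
        np.column_stack([pv, energy]),
        "pve",
        {"pv_amplitude": pv_amplitude, "pv_units": "amplitude" if pv_amplitude else "s"},
    )


def _haar_coefficients(w: np.ndarray, levels: int) -> np.ndarray:
    """Multi-level Haar coefficients per row, zero-padded to a power of two."""
    n, p = w.shape
    padded_len = 1 << (p - 1).bit_length()
    if padded_len < (1 << levels):
        raise ValueError(f"p={p} too short for {levels} decomposition levels")
    padded = np.zeros((n, padded_len))
    padded[:, :p] = w
    coeffs = pywt.wavedec(padded, "haar", level=levels, axis=1)
    return np.concatenate(coeffs, axis=1)


def features_wavelet2(
    x: Union[np.ndarray, LabeledWaveformSet], levels: int = 4, wavelet: str = "haar"
) -> Embedding2D:
    """Wavelet-coefficient features: the two most non-normal coefficients.

    Each waveform is zero-padded to the next power of two and decomposed
    with a multi-level discrete wavelet transform (Haar, 4 levels by
    default).  Across the set, each coefficient's empirical distribution
    is scored by its Kolmogorov-Smirnov distance to a normal fitted by
    moments; the two highest-scoring coefficients become the 2-D
    features.  Multimodal (cluster-bearing) coefficients score high.
    ``params['selected']`` records the chosen coefficient indices.
    """
    w = _waveform_matrix(x)
    if w.shape[0] < 10:
        raise ValueError("need at least 10 waveforms for stable selection")
    if wavelet == "haar":
        coeffs = _haar_coefficients(w, levels)
    else:
        p = w.shape[1]
        padded_len = 1 << (p - 1).bit_length()
        padded = np.zeros((w.shape[0], padded_len))
        padded[:, :p] = w
        coeffs = np.concatenate(
            pywt.wavedec(padded, wavelet, level=levels, axis=1), axis=1
        )
    scores = np.zeros(coeffs.shape[1])
    for j in range(coeffs.shape[1]):
        col = coeffs[:, j]
        sd = col.std()
        if sd == 0:
            continue  # constant coefficient: carries no structure
        scores[j] = stats.kstest(col, "norm", args=(col.mean(), sd)).statistic
    selected = np.argsort(scores)[::-1][:2]
    return Embedding2D(
        coeffs[:, selected],
        "wavelet",
        {
            "levels": levels,
            "wavelet": wavelet,
            "selected": selected.tolist(),
            "ks_scores": scores[selected].tolist(),
        },
    )


def project_tsne(
    x: Union[np.ndarray, LabeledWaveformSet],
    perplexity: float = 30.0,
    learning_rate: float = 500.0,
    iterations: int = 2000,
    seed: int = 0,
) -> Embedding2D:
    """t-SNE embedding of the waveforms.

    Minimizes the Kullback-Leibler divergence between upspace Gaussian
    neighbor probabilities (bandwidths set by ``perplexity``) and
    downspace Student-t probabilities.  Defaults follow the standard
    spike-visualization setting: perplexity 30, learning rate 500, 2000
    iterations.  Small template-level sets call for perplexity 2-3.
    Stochastic but reproducible for a fixed seed.
    """
    w = _waveform_matrix(x)
    n = w.shape[0]
    if perplexity <= 0 or n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} infeasible for n={n}: need n > 3*perplexity"
        )
    model = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        max_iter=iterations,
        init="pca",
        random_state=int(seed) % (2**31),
    )
    coords = model.fit_transform(w)
    return Embedding2D(
        coords,
        "tsne",
        {
            "perplexity": perplexity,
            "learning_rate": learning_rate,
            "iterations": iterations,
            "seed": int(seed),
            "kl_divergence": float(model.kl_divergence_),
        },
    )


def _sammon_stress_and_grads(
    dup: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Stress, gradient, and Sammon's diagonal-Hessian magnitude at y.

    ``dup`` is the (strictly positive off-diagonal) upspace distance
    matrix; the diagonal is ignored.
    """
    eps = 1e-12
    n = dup.shape[0]
    dup = dup + np.eye(n)  # harmless diagonal, avoids 0/0 below
    ddown = squareform(pdist(y)) + np.eye(n)
    ddown = np.maximum(ddown, eps)
    c = dup[np.triu_indices(n, 1)].sum()
    diff = dup - ddown
    np.fill_diagonal(diff, 0.0)
    stress = float((diff**2 / dup)[np.triu_indices(n, 1)].sum()) / c
    inv = 1.0 / (dup * ddown)
    np.fill_diagonal(inv, 0.0)
    delta = y[:, None, :] - y[None, :, :]  # n x n x 2
    grad = (-2.0 / c) * np.einsum("ij,ijq->iq", inv * diff, delta)
    hess_term = (
        diff[:, :, None]
        - (delta**2 / ddown[:, :, None]) * (1.0 + diff / ddown)[:, :, None]
    )
    hess = (-2.0 / c) * np.einsum("ijq->iq", inv[:, :, None] * hess_term)
    return stress, grad, np.abs(hess)


def project_sammon(
    x: Union[np.ndarray, LabeledWaveformSet],
    iterations: int = 500,
    step: float = 0.3,
    seed: int = 0,
    tol: float = 1e-12,
) -> Embedding2D:
    """Sammon mapping: stress-minimizing nonlinear 2-D embedding.

    Minimizes E = (1 / sum D_ij) * sum (D_ij - d_ij)^2 / D_ij over
    downspace configurations, weighting each pair by the inverse of its
    upspace distance D_ij so local structure dominates.  Optimization is
    Sammon's diagonal-Newton descent from a PCA initialization with a
    step-halving safeguard, so the reported stress sequence is monotone
    non-increasing.  Duplicate upspace rows are jittered by 1e-9 of the
    data scale (zero upspace distances are inadmissible in the stress).
    ``params['stress']`` holds the final stress.
    """
    w = np.array(_waveform_matrix(x), dtype=float)
    n = w.shape[0]
    if n < 3:
        raise ValueError("Sammon mapping needs n >= 3")
    rng = np.random.default_rng(int(seed) % (2**31))
    scale = np.abs(w).max() or 1.0
    # Jitter exact duplicates: zero upspace distances break the stress.
    dup = squareform(pdist(w))
    while np.any(dup[np.triu_indices(n, 1)] == 0):
        rows = np.unique(np.where((dup == 0) & ~np.eye(n, dtype=bool))[0])
        w[rows] += rng.normal(scale=1e-9 * scale, size=(rows.size, w.shape[1]))
        dup = squareform(pdist(w))

    if w.shape[1] >= 2 and np.linalg.matrix_rank(w - w.mean(axis=0)) >= 2:
        y = project_pca2(w).coords.copy()
    else:
        y = rng.normal(scale=scale, size=(n, 2))

    stress, grad, hess = _sammon_stress_and_grads(dup, y)
    history = [stress]
    fails = 0
    for _ in range(iterations):
        if stress <= tol:
            break
        direction = grad / np.maximum(hess, 1e-12)
        cur = step
        improved = False
        for _half in range(30):
            y_new = y - cur * direction
            s_new, g_new, h_new = _sammon_stress_and_grads(dup, y_new)
            if s_new <= stress:
                y, stress, grad, hess = y_new, s_new, g_new, h_new
                improved = True
                break
            cur *= 0.5
        history.append(stress)
        if not improved:
            fails += 1
            if fails >= 3:
                raise RuntimeError(
                    f"Sammon mapping diverged: stress stuck at {stress:.3e} "
                    "after repeated step-halving failures"
                )
        else:
            fails = 0
        if len(history) > 2 and history[-2] - history[-1] < tol:
            break
    return Embedding2D(
        y,
        "sammon",
        {
            "stress": float(stress),
            "iterations_run": len(history) - 1,
            "step": step,
            "seed": int(seed),
        },
    )


_METHODS = {
    "pca": project_pca2,
    "pve": features_pv_e,
    "wavelet": features_wavelet2,
    "tsne": project_tsne,
    "sammon": project_sammon,
}


def embed(
    x: Union[np.ndarray, LabeledWaveformSet], method: str, **kwargs
) -> Embedding2D:
    """Dispatch to one of the five 2-D representations by tag."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    return _METHODS[method](x, **kwargs)
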