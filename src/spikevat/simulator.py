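"""Synthetic labeled spike-mixture generator.

Emulates the classic simulated-extracellular-trace protocol: single-unit
spikes are scaled copies of unit templates with amplitudes drawn from a
normal distribution of mean 1.1 hard-truncated to [0.9, 2]; background
noise is built by superimposing thousands of template instances at random
times and rescaling the trace to a standard deviation of 0.1; multi-unit
activity superimposes 20 designated waveform shapes with normalized
amplitudes capped at 0.5.  Spike windows are 2 ms long (48 samples at
24 kHz, 80 at 40 kHz).

Real recordings use template libraries compiled from in-vivo data; here
templates are a parametric two-lobe Gaussian family, which keeps the
generator self-contained and makes between-unit similarity controllable.

Two operating modes:

* waveform-level (:func:`assemble_mixture`): noise is added per extracted
  window — fast, the default for downstream evaluation;
* trace-level (:func:`synth_trace_and_detect`): a continuous trace is
  synthesized and spikes recovered by voltage thresholding, for fidelity
  to the acquisition pipeline.

All generators are seed-deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data import LabeledWaveformSet, window_length


@dataclass(frozen=True)
class AmplitudeModel:
    """Truncated-normal single-unit amplitude law.

    Amplitudes are drawn from Normal(mean, sd) and rejected outside
    [lo, hi] — hard rejection, never clipping, so no probability mass
    accumulates at the bounds.
    """

    mean: float = 1.1
    sd: float = 0.3
    lo: float = 0.9
    hi: float = 2.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("truncation bounds must be ordered lo < hi")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class SpikeTemplate:
    """A unit template: a length-p waveform normalized to unit peak amplitude."""

    shape: np.ndarray
    sampling_rate: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.shape, dtype=float)
        top = np.abs(s).max()
        if top == 0:
            raise ValueError("template is identically zero")
        object.__setattr__(self, "shape", s / top)

    @property
    def p(self) -> int:
        return self.shape.size


@dataclass
class MixtureSpec:
    """Recipe for one synthetic labeled mixture."""

    unit_templates: Sequence[SpikeTemplate]
    spikes_per_unit: Sequence[int]
    amplitude_model: AmplitudeModel = AmplitudeModel()
    noise_sd: float = 0.1
    include_multiunit: bool = False
    multiunit_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.unit_templates) != len(self.spikes_per_unit):
            raise ValueError("one spike count per unit template required")
        if any(c < 1 for c in self.spikes_per_unit):
            raise ValueError("spikes_per_unit entries must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.include_multiunit and self.multiunit_count < 1:
            raise ValueError("multiunit_count must be >= 1 when included")


def _child_rngs(seed: int, count: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]


def _two_lobe_shape(p: int, rng: np.random.Generator) -> np.ndarray:
    """Difference of two Gaussian lobes: valley then after-peak (or inverted)."""
    t = np.arange(p)
    t1 = rng.uniform(0.25 * p, 0.55 * p)
    t2 = t1 + rng.uniform(0.08 * p, 0.3 * p)
    s1 = rng.uniform(0.02 * p, 0.08 * p)
    s2 = rng.uniform(0.04 * p, 0.14 * p)
    a1 = rng.uniform(0.7, 1.3)
    a2 = rng.uniform(0.3, 0.9)
    shape = -a1 * np.exp(-0.5 * ((t - t1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((t - t2) / s2) ** 2
    )
    if rng.random() < 0.3:
        shape = -shape
    return shape


def zero_lag_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized zero-lag cross-correlation of two waveforms."""
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def make_templates(
    k: int,
    p: int = 48,
    sampling_rate: float = 24000.0,
    seed: int = 0,
    max_correlation: float = 0.999,
) -> list[SpikeTemplate]:
    """Draw k pairwise-distinct unit templates.

    Each template is a difference of two Gaussian lobes with randomized
    positions, widths and polarity inside the window, normalized to unit
    maximum absolute amplitude.  Distinctness means every pairwise
    zero-lag normalized correlation is below ``max_correlation``; a
    colliding draw is retried up to 100 times.
    """
    if k < 1 or p < 16:
        raise ValueError("need k >= 1 and p >= 16")
    rng = np.random.default_rng(seed)
    templates: list[SpikeTemplate] = []
    for i in range(k):
        for attempt in range(100):
            shape = _two_lobe_shape(p, rng)
            cand = SpikeTemplate(shape, sampling_rate, {"index": i})
            if all(
                zero_lag_correlation(cand.shape, t.shape) < max_correlation
                for t in templates
            ):
                templates.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw a template distinct from the first {i} in 100 tries"
            )
    return templates


def draw_amplitudes(
    model: AmplitudeModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample n amplitudes from the truncated-normal law."""
    nearest = min(abs(model.mean - model.lo), abs(model.mean - model.hi))
    if model.sd == 0:
        if not model.lo <= model.mean <= model.hi:
            raise ValueError("degenerate amplitude model outside bounds")
        return np.full(n, model.mean)
    if (model.mean < model.lo or model.mean > model.hi) and nearest > 10 * model.sd:
        raise ValueError("truncation bounds exclude the mean by > 10 sd")
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(model.mean, model.sd, size=max(n, 256))
        out = np.concatenate([out, draw[(draw >= model.lo) & (draw <= model.hi)]])
    return out[:n]


def background_noise(
    n_samples: int,
    templates: Sequence[SpikeTemplate],
    target_sd: float = 0.1,
    seed: int = 0,
    n_events: Optional[int] = None,
) -> np.ndarray:
    """Structured background-noise trace with an exactly rescaled SD.

    Superimposes at least 1000 template instances at uniform random
    offsets (partial overlap at the trace edges allowed) onto a zero
    trace, then rescales deterministically so the empirical population
    standard deviation equals ``target_sd``.  Because the noise is built
    from smooth spike shapes it is temporally correlated, unlike white
    noise.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if target_sd < 0:
        raise ValueError("target_sd must be nonnegative")
    if not templates:
        raise ValueError("need at least one template")
    rng = np.random.default_rng(seed)
    p = templates[0].p
    if n_events is None:
        n_events = max(1000, 2 * n_samples // p)
    n_events = max(n_events, 1000)
    trace = np.zeros(n_samples)
    shapes = [t.shape for t in templates]
    picks = rng.integers(0, len(shapes), size=n_events)
    offsets = rng.integers(-p + 1, n_samples, size=n_events)
    for which, off in zip(picks, offsets):
        s = shapes[which]
        lo = max(off, 0)
        hi = min(off + p, n_samples)
        trace[lo:hi] += s[lo - off : hi - off]
    sd = trace.std()
    if sd == 0:
        raise ValueError("zero-variance pre-scale trace")
    if target_sd == 0:
        return np.zeros(n_samples)
    return trace * (target_sd / sd)


def synth_unit_spikes(
    template: SpikeTemplate,
    n: int,
    amplitude_model: AmplitudeModel = AmplitudeModel(),
    noise_sd: float = 0.1,
    seed: int = 0,
    noise_templates: Optional[Sequence[SpikeTemplate]] = None,
) -> np.ndarray:
    """Synthesize n single-unit spikes: amplitude-scaled template + noise.

    Each spike is ``a * shape + eps`` with ``a`` from the truncated-normal
    amplitude law and ``eps`` a window sliced from a background-noise
    trace whose population SD equals ``noise_sd``.  ``noise_templates``
    defaults to a bank of 20 shapes drawn from the same seed stream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    amp_rng, noise_seed_rng, slice_rng = _child_rngs(seed, 3)
    amps = draw_amplitudes(amplitude_model, n, amp_rng)
    spikes = amps[:, None] * template.shape[None, :]
    if noise_sd > 0:
        p = template.p
        if noise_templates is None:
            noise_templates = make_templates(
                20, p, template.sampling_rate,
                seed=int(noise_seed_rng.integers(2**31)),
            )
        trace = background_noise(
            n_samples=(n + 2) * p,
            templates=noise_templates,
            target_sd=noise_sd,
            seed=int(noise_seed_rng.integers(2**31)),
        )
        offsets = slice_rng.integers(0, trace.size - p + 1, size=n)
        noise = np.stack([trace[o : o + p] for o in offsets])
        spikes = spikes + noise
    return spikes


def synth_multiunit(
    templates: Sequence[SpikeTemplate],
    n: int,
    seed: int = 0,
    amplitude_range: tuple[float, float] = (0.3, 0.5),
) -> np.ndarray:
    """Multi-unit activity: 20 designated low-amplitude waveform shapes.

    Each multi-unit spike is one of 20 designated shapes scaled by an
    amplitude drawn uniformly from ``amplitude_range`` (capped at 0.5 by
    default).  If fewer than 20 templates are supplied the designated
    shapes are drawn with replacement.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if amplitude_range[1] > 0.5:
        raise ValueError("multi-unit amplitudes are capped at 0.5")
    if not templates:
        raise ValueError("need at least one template")
    rng = np.random.default_rng(seed)
    if len(templates) >= 20:
        bank = [t.shape for t in templates[:20]]
    else:
        idx = rng.integers(0, len(templates), size=20)
        bank = [templates[i].shape for i in idx]
    picks = rng.integers(0, 20, size=n)
    amps = rng.uniform(*amplitude_range, size=n)
    return np.stack([amps[i] * bank[picks[i]] for i in range(n)])


def assemble_mixture(spec: MixtureSpec) -> LabeledWaveformSet:
    """Waveform-level mixture: per-unit matrices concatenated and shuffled.

    Unit i's spikes get label i+1; multi-unit activity, when included,
    forms its own labeled subset.  Row order is shuffled by the spec
    seed; the label multiset is preserved.
    """
    k = len(spec.unit_templates)
    rngs = _child_rngs(spec.seed, k + 2)
    fs = spec.unit_templates[0].sampling_rate
    blocks, labels = [], []
    for i, (tpl, count) in enumerate(zip(spec.unit_templates, spec.spikes_per_unit)):
        w = synth_unit_spikes(
            tpl,
            count,
            spec.amplitude_model,
            spec.noise_sd,
            seed=int(rngs[i].integers(2**31)),
        )
        blocks.append(w)
        labels.append(np.full(count, i + 1))
    if spec.include_multiunit:
        blocks.append(
            synth_multiunit(
                spec.unit_templates,
                spec.multiunit_count,
                seed=int(rngs[k].integers(2**31)),
            )
        )
        labels.append(np.full(spec.multiunit_count, k + 1))
    waveforms = np.vstack(blocks)
    label_vec = np.concatenate(labels)
    perm = rngs[k + 1].permutation(waveforms.shape[0])
    return LabeledWaveformSet(
        waveforms[perm], fs, label_vec[perm], {"seed": spec.seed}
    )


@dataclass(frozen=True)
class DetectionResult:
    """Thresholding outcome: extracted windows plus a detection report."""

    waveforms: LabeledWaveformSet
    planted_times: np.ndarray
    detected_times: np.ndarray
    missed: np.ndarray          # planted event times that no window matched
    false_positives: np.ndarray  # detected times with no planted event nearby


def synth_trace_and_detect(
    spec: MixtureSpec,
    duration_s: float,
    threshold_sds: float = 5.0,
    window_s: float = 0.002,
) -> DetectionResult:
    """Trace-level simulation with threshold detection.

    Builds a continuous trace (background noise at the spec's noise SD
    plus amplitude-scaled unit spikes at random non-overlapping times),
    detects absolute-voltage crossings of ``threshold_sds * noise_sd``,
    extracts windows of ``window_s`` centered on the local absolute
    extremum, and labels each window by the planted unit generating it
    (label 0 marks a detection with no planted event: a false positive).
    At the default settings every planted single-unit spike (amplitude
    >= 0.9) crosses the 0.5 threshold.
    """
    k = len(spec.unit_templates)
    fs = spec.unit_templates[0].sampling_rate
    p = spec.unit_templates[0].p
    win = window_length(window_s, fs)
    n_samples = int(round(duration_s * fs))
    total_spikes = int(sum(spec.spikes_per_unit))
    if n_samples < (total_spikes + 2) * 2 * p:
        raise ValueError("duration too short for the requested spike counts")

    rngs = _child_rngs(spec.seed, 4)
    if spec.noise_sd > 0:
        trace = background_noise(
            n_samples,
            spec.unit_templates,
            target_sd=spec.noise_sd,
            seed=int(rngs[0].integers(2**31)),
        )
    else:
        trace = np.zeros(n_samples)

    # Non-overlapping placement: slot the events at least one window apart.
    slot = 2 * p
    n_slots = n_samples // slot - 2
    if n_slots < total_spikes:
        raise ValueError("infeasible placement at refractory spacing")
    chosen = rngs[1].choice(n_slots, size=total_spikes, replace=False)
    starts = np.sort(chosen * slot + p)
    assign = np.repeat(np.arange(1, k + 1), spec.spikes_per_unit)
    rngs[1].shuffle(assign)

    planted_t, planted_label = [], []
    for start, unit in zip(starts, assign):
        tpl = spec.unit_templates[unit - 1]
        amp = draw_amplitudes(spec.amplitude_model, 1, rngs[2])[0]
        trace[start : start + p] += amp * tpl.shape
        ext = start + int(np.argmax(np.abs(tpl.shape)))
        planted_t.append(ext)
        planted_label.append(unit)
    planted_t = np.asarray(planted_t)
    planted_label = np.asarray(planted_label)

    threshold = threshold_sds * spec.noise_sd
    above = np.abs(trace) > threshold
    detected_times, windows, labels = [], [], []
    i = 0
    half = win // 2
    while i < n_samples:
        if above[i]:
            seg_end = min(i + win, n_samples)
            center = i + int(np.argmax(np.abs(trace[i:seg_end])))
            lo = center - half
            hi = lo + win
            if lo >= 0 and hi <= n_samples:
                detected_times.append(center)
                windows.append(trace[lo:hi])
                near = np.flatnonzero(np.abs(planted_t - center) <= half)
                labels.append(int(planted_label[near[0]]) if near.size else 0)
            i = hi  # refractory skip past this window
        else:
            i += 1
    detected_times = np.asarray(detected_times, dtype=int)
    matched = (
        np.asarray(
            [np.any(np.abs(detected_times - t) <= half) for t in planted_t]
        )
        if detected_times.size
        else np.zeros(planted_t.size, dtype=bool)
    )
    waveforms = (
        np.stack(windows) if windows else np.empty((0, win))
    )
    labels = np.asarray(labels, dtype=int)
    return DetectionResult(
        waveforms=LabeledWaveformSet(waveforms, fs, labels if labels.size else None),
        planted_times=planted_t,
        detected_times=detected_times,
        missed=planted_t[~matched],
        false_positives=detected_times[
            [l == 0 for l in labels]
        ] if detected_times.size else detected_times,
    )


def enumerate_mixtures(
    n_subsets: int, k_min: int, k_max: int
) -> list[tuple[int, ...]]:
    """All subset-index combinations of sizes k_min..k_max, lexicographic.

    Nine subsets combined at k = 2..9 give the classic 502 mixtures
    (36 + 84 + 126 + 126 + 84 + 36 + 9 + 1).
    """
    if not 1 <= k_min <= k_max <= n_subsets:
        raise ValueError("need 1 <= k_min <= k_max <= n_subsets")
    combos: list[tuple[int, ...]] = []
    for k in range(k_min, k_max + 1):
        combos.extend(itertools.combinations(range(n_subsets), k))
    return combos
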