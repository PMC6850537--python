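"""Core data containers for spike-waveform sets.

A spike waveform set is an ``n x p`` matrix: one row per detected spike,
one column per voltage sample.  At the conventional 2 ms window this gives
48 samples at 24 kHz or 80 samples at 40 kHz.  Ground-truth unit labels,
when known, ride along as a crisp partition-compatible integer vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class LabeledWaveformSet:
    """A set of spike waveforms with an optional ground-truth labeling.

    Parameters
    ----------
    waveforms : ndarray of shape (n, p)
        Voltage samples per spike.  Dimensionless for simulated data,
        microvolts for recorded data.
    sampling_rate : float
        Sampling rate in Hz.
    labels : ndarray of shape (n,), optional
        Integer unit label per spike (ground truth), if known.
    """

    waveforms: np.ndarray
    sampling_rate: float
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if self.waveforms.ndim != 2:
            raise ValueError("waveforms must be a 2-D (n x p) matrix")
        if not np.all(np.isfinite(self.waveforms)):
            raise ValueError("waveforms contain non-finite entries")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.n,):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match n={self.n}"
                )

    @property
    def n(self) -> int:
        """Number of spikes."""
        return self.waveforms.shape[0]

    @property
    def p(self) -> int:
        """Number of voltage samples per spike (upspace dimension)."""
        return self.waveforms.shape[1]

    @property
    def duration(self) -> float:
        """Window duration in seconds (p / sampling_rate)."""
        return self.p / self.sampling_rate

    def subset(self, rows: np.ndarray) -> "LabeledWaveformSet":
        """Row-subset the set, carrying labels along."""
        rows = np.asarray(rows)
        return LabeledWaveformSet(
            self.waveforms[rows],
            self.sampling_rate,
            None if self.labels is None else self.labels[rows],
            dict(self.meta),
        )


def window_length(duration_s: float, sampling_rate: float) -> int:
    """Number of samples in a spike window of the given duration.

    2 ms at 24 kHz -> 48 samples; 2 ms at 40 kHz -> 80 samples.
    """
    return int(round(duration_s * sampling_rate))
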