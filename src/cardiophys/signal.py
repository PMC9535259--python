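"""Uniformly sampled physiological traces.

:class:`SampledSignal` is the shared currency of every analysis module:
surface-lead ECG (mV), whole-cell current-clamp membrane potential (mV) and
whole-body plethysmography flow (arbitrary units).  Time is kept in seconds
internally; interval results are converted to milliseconds only at the
reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = ["SampledSignal"]


@dataclass
class SampledSignal:
    """A uniformly sampled real-valued trace.

    Parameters
    ----------
    samples
        1-D array of sample values (mV for voltage, arbitrary units for
        respiratory flow).
    sampling_rate
        Sampling rate in Hz, strictly positive.
    start_time
        Time of the first sample in seconds.
    channel_label
        Free-text channel description (e.g. ``"lead II"``).
    units
        Free-text physical units of the samples (e.g. ``"mV"``).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    channel_label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be a positive, finite number")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def dt(self) -> float:
        """Sample spacing in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Span from first to last sample, ``(n - 1) / rate`` seconds."""
        return (self.n_samples - 1) / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float, clip: bool = True) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        i = int(round((t - self.start_time) * self.sampling_rate))
        if clip:
            i = min(max(i, 0), self.n_samples - 1)
        return i

    def slice_time(self, t0: float, t1: float) -> "SampledSignal":
        """Sub-signal covering ``[t0, t1)`` (clipped to the record)."""
        i0 = max(0, int(np.ceil((t0 - self.start_time) * self.sampling_rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((t1 - self.start_time) * self.sampling_rate - 1e-9)))
        if i1 <= i0:
            raise ValidationError("empty time slice")
        return replace(
            self,
            samples=self.samples[i0:i1].copy(),
            start_time=self.start_time + i0 / self.sampling_rate,
        )
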