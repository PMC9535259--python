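"""Synthetic mouse lead-II ECG with analytically known fiducials.

Each complex is a sum of compactly supported raised-cosine (Hann) lobes:
P wave, a single dominant QRS lobe, an optional J wave in the ST gap, and a
T wave.  Compact support makes every nominal onset/offset an exact property
of the construction:

* QRS spans ``[r - qrs/2, r + qrs/2]``.
* P onset is at ``qrs_onset - PR`` (lobe width ``p_width``).
* The QT end target is the post-peak point where the T lobe has fallen to
  10% of its height: for a Hann lobe that is at ``0.89758`` of its width,
  so the T lobe is placed such that this point lands exactly at
  ``qrs_onset + qt``.

Beat-to-beat RR jitter is Gaussian; optional breathing-interference bursts
are band-limited (100-500 Hz) noise epochs, the same morphology the clean-
complex selector is designed to reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.signal as sig

from ..errors import ValidationError
from ..signal import SampledSignal

__all__ = ["ECGGenParams", "generate_ecg", "HANN_TEN_PCT_RETURN"]

#: fraction of a Hann lobe's width at which it falls to 10% of peak height,
#: past the peak: 1 - acos(0.8) / (2 pi)
HANN_TEN_PCT_RETURN = 1.0 - math.acos(0.8) / (2.0 * math.pi)


@dataclass
class ECGGenParams:
    """Generator parameters; interval defaults follow healthy adult female
    mouse values under isoflurane anesthesia."""

    rr_mean: float = 154.4        # ms
    rr_sd: float = 3.1            # ms, beat-to-beat jitter
    pr: float = 46.1              # ms, P onset -> QRS onset
    qrs: float = 12.3             # ms
    qt: float = 53.3              # ms, QRS onset -> QT end
    p_amp: float = 0.10           # mV
    p_width: float = 14.0         # ms
    r_amp: float = 1.0            # mV
    j_amp: float = 0.22           # mV
    j_width: float = 8.0          # ms
    t_amp: float = 0.30           # mV
    t_width: float = 25.0         # ms
    j_wave_present: bool = True
    noise_sd: float = 0.01        # mV, white
    interference_bursts: list = field(default_factory=list)  # (start s, dur s, rms mV)
    sampling_rate: float = 2000.0
    n_beats: int = 20
    seed: int | None = None

    def validate(self) -> None:
        if not (self.pr < self.qt < self.rr_mean):
            raise ValidationError("require pr < qt < rr_mean")
        for name in ("qrs", "p_width", "j_width", "t_width"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.rr_sd < 0 or self.noise_sd < 0:
            raise ValidationError("spreads must be non-negative")
        if self.p_width >= self.pr:
            raise ValidationError("P lobe must fit inside the PR interval")
        t_start = self.qt - HANN_TEN_PCT_RETURN * self.t_width
        if t_start <= self.qrs:
            raise ValidationError("T lobe must start after QRS end; shorten "
                                  "t_width or lengthen qt")
        if self.j_wave_present and self.j_amp > 0 and \
                self.qrs + 1.0 + self.j_width >= t_start:
            raise ValidationError("J lobe does not fit between QRS end and T")
        if self.sampling_rate < 1000:
            raise ValidationError("generate at >= 1 kHz")
        if self.n_beats < 1:
            raise ValidationError("need at least one beat")


def _hann_lobe(t: np.ndarray, start: float, width: float, amp: float
               ) -> np.ndarray:
    tau = (t - start) / width
    y = np.zeros_like(t)
    m = (tau > 0) & (tau < 1)
    y[m] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau[m]))
    return y


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float],
                       rms: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    hi = min(band[1], 0.45 * fs)
    sos = sig.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    y = sig.sosfiltfilt(sos, white)
    cur = np.sqrt(np.mean(y ** 2))
    return y * (rms / cur) if cur > 0 else y


def generate_ecg(params: ECGGenParams) -> tuple[SampledSignal, pd.DataFrame]:
    """Synthesize an ECG and its per-beat ground truth.

    The truth table columns: ``r_time, p_onset, qrs_onset, qrs_end, qt_end,
    t_peak, rr_ms, pr_ms, qrs_ms, qt_ms, j_amp_mv`` (times in seconds; the
    last beat's ``rr_ms`` refers to the spacing to a virtual next beat used
    to size the record).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate

    rr_s = np.maximum(
        (params.rr_mean + params.rr_sd * rng.standard_normal(params.n_beats)) * 1e-3,
        (params.qt + 20.0) * 1e-3)
    first_r = 0.25
    r_times = first_r + np.concatenate([[0.0], np.cumsum(rr_s[:-1])])
    total = r_times[-1] + rr_s[-1]
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs
    x = np.zeros(n)

    ms = 1e-3
    qrs_half = params.qrs / 2.0 * ms
    t_start_rel = (params.qt - HANN_TEN_PCT_RETURN * params.t_width) * ms
    rows = []
    for k, r in enumerate(r_times):
        onset = r - qrs_half
        end = r + qrs_half
        x += _hann_lobe(t, onset, params.qrs * ms, params.r_amp)
        p_onset = onset - params.pr * ms
        x += _hann_lobe(t, p_onset, params.p_width * ms, params.p_amp)
        t_lobe_start = onset + t_start_rel
        x += _hann_lobe(t, t_lobe_start, params.t_width * ms, params.t_amp)
        j_on = float("nan")
        if params.j_wave_present and params.j_amp > 0:
            j_on = end + 1.0 * ms
            x += _hann_lobe(t, j_on, params.j_width * ms, params.j_amp)
        rows.append({
            "beat": k,
            "r_time": r,
            "p_onset": p_onset,
            "qrs_onset": onset,
            "qrs_end": end,
            "t_peak": t_lobe_start + params.t_width / 2.0 * ms,
            "qt_end": onset + params.qt * ms,
            "rr_ms": rr_s[k] * 1e3,
            "pr_ms": params.pr,
            "qrs_ms": params.qrs,
            "qt_ms": params.qt,
            "j_amp_mv": params.j_amp if (params.j_wave_present and params.j_amp > 0)
                        else float("nan"),
        })

    if params.noise_sd > 0:
        x += params.noise_sd * rng.standard_normal(n)
    for start, dur, rms in params.interference_bursts:
        i0, i1 = int(start * fs), min(int((start + dur) * fs), n)
        if i1 <= i0:
            continue
        burst = _bandlimited_noise(i1 - i0, fs, (100.0, 500.0), rms, rng)
        burst *= sig.windows.tukey(i1 - i0, alpha=0.2)
        x[i0:i1] += burst

    signal = SampledSignal(samples=x, sampling_rate=fs, start_time=0.0,
                           channel_label="lead II (synthetic)", units="mV")
    return signal, pd.DataFrame(rows)
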