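"""Murine ECG delineation, interval measurement and rate correction.

The pipeline is: R-peak detection on a 10-300 Hz band-passed trace with
automatic polarity handling -> selection of a run of consecutive complexes
free of breathing interference (scored as RMS of the 100-500 Hz band over
the beat window) -> per-complex delineation of QRS onset/end, J wave,
T peak and QT end -> per-complex intervals (RR, HR, PR, QRS, QT) and the
two rodent rate corrections:

* ``qtc_mitchell``:  QTc = QT / sqrt(RR / 100)   (reference RR 100 ms)
* ``qtc_mccauley``:  QTc = QT + 0.3173 * (170 - RR)  (reference RR 170 ms)

Operational fiducial definitions (all configurable):

* QRS onset (end): the last point before (first after) the maximal absolute
  derivative of the band-passed complex at which that derivative falls
  below 10% of its beat maximum.
* Isoelectric baseline: median over a 10 ms window ending 5 ms before QRS
  onset.
* QT end: first return of the (lightly smoothed) trace, after the T peak,
  to within 10% of the T-peak height above baseline.
* J wave: reported only when its peak between QRS end and the T search
  window exceeds 0.05 mV above baseline.
* P wave: best effort; PR is reported missing when no P deflection exceeds
  twice the baseline noise SD (with a small absolute floor).

Intervals are reported in milliseconds; fiducial times stay in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal as sig

from .errors import AnalysisError, FiducialError, ValidationError
from .signal import SampledSignal

__all__ = [
    "ECGConfig",
    "FiducialSet",
    "ECGSummary",
    "detect_r_peaks",
    "select_clean_complexes",
    "delineate_complex",
    "measure_intervals",
    "qtc_mitchell",
    "qtc_mccauley",
    "summarize_animal_ecg",
]


@dataclass
class ECGConfig:
    """Tunables of the ECG analysis; defaults suit anesthetized mouse lead II."""

    detect_band_hz: tuple[float, float] = (10.0, 300.0)
    artefact_band_hz: tuple[float, float] = (100.0, 500.0)
    artefact_threshold_factor: float = 3.0   # x record median moving RMS
    artefact_r_fraction: float = 0.05        # absolute cap, x R-peak amplitude
    artefact_window_ms: tuple[float, float] = (40.0, 70.0)  # before/after R
    artefact_qrs_blank_ms: float = 15.0      # excluded around R when scoring
    refractory_ms: float = 40.0
    peak_height_fraction: float = 0.4        # of the median candidate peak
    auto_polarity: bool = True
    qrs_deriv_fraction: float = 0.1          # derivative threshold, of beat max
    qrs_search_ms: float = 30.0
    baseline_window_ms: tuple[float, float] = (15.0, 5.0)  # ends 5 ms pre-onset
    t_return_fraction: float = 0.1
    t_search_gap_ms: float = 12.0            # after QRS end
    t_search_frac_rr: float = 0.7            # window end, fraction of local RR
    t_end_frac_rr: float = 0.9               # crossing search end
    t_min_amplitude_mv: float = 0.05
    t_smooth_ms: float = 3.0
    j_floor_mv: float = 0.05
    j_smooth_ms: float = 1.0
    p_search_ms: float = 60.0
    p_gap_ms: float = 5.0
    p_min_snr: float = 2.0
    p_floor_mv: float = 0.02
    n_complexes: int = 5


@dataclass(frozen=True)
class FiducialSet:
    """Per-complex fiducial times (s) and J amplitude (mV); NaN = absent."""

    r_peak_time: float
    qrs_onset_time: float
    qrs_end_time: float
    t_peak_time: float
    qt_end_time: float
    p_onset_time: float = float("nan")
    j_peak_amplitude: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.qrs_onset_time <= self.r_peak_time <= self.qrs_end_time
                <= self.t_peak_time <= self.qt_end_time):
            raise ValidationError("fiducial ordering violated within complex")
        if np.isfinite(self.p_onset_time) and self.p_onset_time >= self.qrs_onset_time:
            raise ValidationError("P onset must precede QRS onset")


@dataclass
class ECGSummary:
    """Animal-level means over the selected run of consecutive clean complexes."""

    rr_ms: float
    hr_bpm: float
    pr_ms: float
    qrs_ms: float
    qt_ms: float
    qtc_mitchell_ms: float
    qtc_mccauley_ms: float
    j_wave_mv: float
    n_complexes: int
    first_beat_index: int
    per_beat: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------- filtering

def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 3
              ) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)  # keep the upper edge below Nyquist
    sos = sig.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sig.sosfiltfilt(sos, x)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    n = max(int(n), 1)
    if n == 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def _savgol_derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """5-point quadratic Savitzky-Golay first derivative, in units per second."""
    if x.size < 5:
        return np.gradient(x) * fs
    return sig.savgol_filter(x, 5, 2, deriv=1) * fs


def _interp_crossing_below(y: np.ndarray, start: int, stop: int, level: float,
                           step: int = 1) -> float | None:
    """Fractional index where ``y`` first drops below ``level`` walking from
    ``start`` toward ``stop`` with ``step`` (+1 forward / -1 backward)."""
    prev = start
    for i in range(start, stop, step):
        if y[i] < level:
            y0, y1 = y[prev], y[i]
            if y0 == y1:
                return float(i)
            frac = (y0 - level) / (y0 - y1)
            return prev + frac * (i - prev)
        prev = i
    return None


# ---------------------------------------------------------------- detection

def detect_r_peaks(signal: SampledSignal, config: ECGConfig | None = None
                   ) -> np.ndarray:
    """Times (s) of R peaks, strictly increasing, refractory-spaced >= 40 ms."""
    config = config or ECGConfig()
    if signal.sampling_rate < 1000:
        raise ValidationError("ECG analysis requires a sampling rate >= 1 kHz")
    if signal.duration < 2.0:
        raise AnalysisError("ECG record must span at least 2 s")

    xf = _bandpass(signal.samples, signal.sampling_rate, config.detect_band_hz)
    if config.auto_polarity and abs(xf.min()) > abs(xf.max()):
        xf = -xf
    distance = max(int(config.refractory_ms * 1e-3 * signal.sampling_rate), 1)
    # two-stage adaptive threshold: refractory-spaced local maxima first,
    # then keep peaks above a fraction of the upper peak-height quantile
    # (robust to records where waves fill most of the cycle and to a
    # minority of oversized artefact deflections)
    idx, props = sig.find_peaks(xf, distance=distance, height=0.0)
    if idx.size == 0 or float(np.max(props["peak_heights"])) <= 0.0:
        warnings.warn("no R peaks above the adaptive threshold", stacklevel=2)
        return np.asarray([], dtype=float)
    ref = float(np.percentile(props["peak_heights"], 90))
    sigma = 1.4826 * float(np.median(np.abs(xf)))
    if ref <= 2.0 * sigma:
        warnings.warn("no R peaks above the adaptive threshold", stacklevel=2)
        return np.asarray([], dtype=float)
    threshold = config.peak_height_fraction * ref
    idx = idx[props["peak_heights"] >= threshold]
    return signal.start_time + idx / signal.sampling_rate


def _artefact_scores(signal: SampledSignal, r_times: np.ndarray, config: ECGConfig
                     ) -> tuple[np.ndarray, float]:
    fs = signal.sampling_rate
    xa = _bandpass(signal.samples, fs, config.artefact_band_hz)
    win = max(int(0.05 * fs), 2)
    record_rms = np.sqrt(_moving_average(xa ** 2, win))
    threshold = config.artefact_threshold_factor * float(np.median(record_rms))
    # absolute cap so globally contaminated records are still rejected:
    # a clean beat's out-of-QRS 100-500 Hz RMS is a small fraction of R height
    r_idx = np.clip(((r_times - signal.start_time) * fs).round().astype(int),
                    0, signal.n_samples - 1)
    r_height = float(np.median(np.abs(signal.samples[r_idx])))
    if r_height > 0:
        threshold = min(threshold, config.artefact_r_fraction * r_height)

    pre = config.artefact_window_ms[0] * 1e-3
    post = config.artefact_window_ms[1] * 1e-3
    blank = config.artefact_qrs_blank_ms * 1e-3
    scores = np.empty(r_times.size)
    t = signal.times()
    for k, r in enumerate(r_times):
        inside = (t >= r - pre) & (t <= r + post) & (np.abs(t - r) > blank)
        seg = xa[inside]
        scores[k] = np.sqrt(np.mean(seg ** 2)) if seg.size else np.inf
    return scores, threshold


def select_clean_complexes(signal: SampledSignal, r_times: Sequence[float],
                           n_required: int = 5, config: ECGConfig | None = None
                           ) -> np.ndarray:
    """Indices of the earliest run of ``n_required`` consecutive complexes whose
    breathing-interference score is below threshold."""
    config = config or ECGConfig()
    r_times = np.asarray(r_times, dtype=float)
    if n_required < 1:
        raise ValidationError("n_required must be >= 1")
    if r_times.size < n_required:
        raise AnalysisError(
            f"only {r_times.size} complexes detected, {n_required} required")
    scores, threshold = _artefact_scores(signal, r_times, config)
    clean = scores < threshold
    run = _first_run(clean, n_required)
    if run is None:
        longest = _longest_run(clean)
        raise AnalysisError(
            f"no run of {n_required} consecutive clean complexes; "
            f"longest clean run found: {longest}")
    return np.arange(run, run + n_required)


def _first_run(mask: np.ndarray, n: int) -> int | None:
    count = 0
    for i, ok in enumerate(mask):
        count = count + 1 if ok else 0
        if count >= n:
            return i - n + 1
    return None


def _longest_run(mask: np.ndarray) -> int:
    best = count = 0
    for ok in mask:
        count = count + 1 if ok else 0
        best = max(best, count)
    return best


# -------------------------------------------------------------- delineation

def delineate_complex(signal: SampledSignal, r_time: float, rr_local_ms: float,
                      config: ECGConfig | None = None) -> FiducialSet:
    """Locate the fiducial points of the complex whose R peak is at ``r_time``."""
    config = config or ECGConfig()
    fs = signal.sampling_rate
    x = signal.samples
    t0 = signal.start_time
    rr = rr_local_ms * 1e-3
    r_idx = signal.index_at(r_time)

    xf = _bandpass(x, fs, config.detect_band_hz)
    if config.auto_polarity and abs(xf.min()) > abs(xf.max()):
        xf = -xf
    dmag = np.abs(_savgol_derivative(xf, fs))

    half = int(config.qrs_search_ms * 1e-3 * fs)
    lo = max(r_idx - half, 0)
    hi = min(r_idx + half, x.size - 1)
    if lo >= r_idx or hi <= r_idx:
        raise FiducialError("QRS search window does not fit inside the record")
    dmax = float(dmag[lo:hi + 1].max())
    thr = config.qrs_deriv_fraction * dmax

    i_left = lo + int(np.argmax(dmag[lo:r_idx + 1]))
    on_f = _interp_crossing_below(dmag, i_left, lo - 1 if lo > 0 else -1, thr, -1)
    i_right = r_idx + int(np.argmax(dmag[r_idx:hi + 1]))
    off_f = _interp_crossing_below(dmag, i_right, hi + 1, thr, +1)
    if on_f is None or off_f is None:
        raise FiducialError("QRS bounds not found (derivative never quiets)")
    qrs_onset = t0 + on_f / fs
    qrs_end = t0 + off_f / fs

    b0 = signal.index_at(qrs_onset - config.baseline_window_ms[0] * 1e-3)
    b1 = signal.index_at(qrs_onset - config.baseline_window_ms[1] * 1e-3)
    if b1 <= b0:
        raise FiducialError("baseline window does not fit inside the record")
    baseline = float(np.median(x[b0:b1 + 1]))
    noise_sd = float(np.std(x[b0:b1 + 1]))

    xs = _moving_average(x, int(config.t_smooth_ms * 1e-3 * fs))

    # --- T wave and QT end
    ts0 = signal.index_at(qrs_end + config.t_search_gap_ms * 1e-3)
    ts1 = signal.index_at(min(r_time + config.t_search_frac_rr * rr,
                              signal.end_time))
    if ts1 <= ts0 + 2:
        raise FiducialError("T search window does not fit inside the record")
    tp_idx = ts0 + int(np.argmax(xs[ts0:ts1 + 1]))
    t_height = xs[tp_idx] - baseline
    if t_height < max(config.t_min_amplitude_mv, 3.0 * noise_sd):
        raise FiducialError("T wave undetectable in this complex")
    t_peak = t0 + tp_idx / fs
    level = baseline + config.t_return_fraction * t_height
    te1 = signal.index_at(min(r_time + config.t_end_frac_rr * rr, signal.end_time))
    end_f = _interp_crossing_below(xs, tp_idx, te1 + 1, level, +1)
    if end_f is None:
        raise FiducialError("QT end not found before the next complex")
    qt_end = t0 + end_f / fs

    # --- J wave (optional); measured on a lightly smoothed copy so the
    # narrow lobe's amplitude is not attenuated
    j_amp = float("nan")
    j0 = signal.index_at(qrs_end + 1e-3)
    if ts0 > j0 + 1:
        xj = _moving_average(x, int(config.j_smooth_ms * 1e-3 * fs))
        cand = float(np.max(xj[j0:ts0]) - baseline)
        if cand > config.j_floor_mv:
            j_amp = cand

    # --- P wave (best effort)
    p_onset = float("nan")
    p0 = signal.index_at(qrs_onset - config.p_search_ms * 1e-3)
    p1 = signal.index_at(qrs_onset - config.p_gap_ms * 1e-3)
    if p1 > p0 + 2:
        pk = p0 + int(np.argmax(xs[p0:p1 + 1]))
        p_height = xs[pk] - baseline
        if p_height > max(config.p_min_snr * noise_sd, config.p_floor_mv):
            dsm = _savgol_derivative(xs, fs)
            if pk > p0:
                i_up = p0 + int(np.argmax(dsm[p0:pk + 1]))
                up_max = dsm[i_up]
                if up_max > 0:
                    f = _interp_crossing_below(dsm, i_up, p0 - 1 if p0 > 0 else -1,
                                               config.qrs_deriv_fraction * up_max, -1)
                    if f is not None:
                        p_onset = t0 + f / fs

    return FiducialSet(r_peak_time=r_time, qrs_onset_time=qrs_onset,
                       qrs_end_time=qrs_end, t_peak_time=t_peak,
                       qt_end_time=qt_end, p_onset_time=p_onset,
                       j_peak_amplitude=j_amp)


# -------------------------------------------------------------- intervals

def measure_intervals(fiducials: Sequence[FiducialSet],
                      next_r_time: float | None = None) -> pd.DataFrame:
    """Per-complex intervals (ms) from a sequence of fiducial sets.

    RR_i is the spacing to the next complex; for the final complex it uses
    ``next_r_time`` when supplied and is missing otherwise.
    """
    fids = list(fiducials)
    if len(fids) < 2 and next_r_time is None:
        raise AnalysisError("measure_intervals requires >= 2 complexes for RR")
    r = np.array([f.r_peak_time for f in fids])
    if np.any(np.diff(r) <= 0):
        raise AnalysisError("internal consistency error: R times not increasing")
    nxt = np.append(r[1:], next_r_time if next_r_time is not None else np.nan)
    rr = (nxt - r) * 1e3
    qt = np.array([(f.qt_end_time - f.qrs_onset_time) * 1e3 for f in fids])
    qrs = np.array([(f.qrs_end_time - f.qrs_onset_time) * 1e3 for f in fids])
    pr = np.array([(f.qrs_onset_time - f.p_onset_time) * 1e3 for f in fids])
    j = np.array([f.j_peak_amplitude for f in fids])
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = 60000.0 / rr
        if np.any(qt[np.isfinite(rr)] >= rr[np.isfinite(rr)]):
            raise AnalysisError("internal consistency error: QT >= RR")
    return pd.DataFrame({
        "r_time_s": r, "rr_ms": rr, "hr_bpm": hr, "pr_ms": pr,
        "qrs_ms": qrs, "qt_ms": qt, "j_wave_mv": j,
    })


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError(f"{name} must be positive and finite")
    return arr


def qtc_mitchell(qt_ms, rr_ms):
    """Square-root rate correction normalized to RR = 100 ms:
    QTc = QT / sqrt(RR / 100)."""
    qt = _check_positive("QT", qt_ms)
    rr = _check_positive("RR", rr_ms)
    out = qt / np.sqrt(rr / 100.0)
    return float(out) if out.ndim == 0 else out


def qtc_mccauley(qt_ms, rr_ms):
    """Linear rate correction normalized to RR = 170 ms:
    QTc = QT + 0.3173 * (170 - RR)."""
    qt = _check_positive("QT", qt_ms)
    rr = _check_positive("RR", rr_ms)
    out = qt + 0.3173 * (170.0 - rr)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------- summary

def summarize_animal_ecg(signal: SampledSignal, config: ECGConfig | None = None
                         ) -> ECGSummary:
    """Animal-level ECG summary: means over the earliest clean run of
    ``config.n_complexes`` consecutive complexes, QTc computed per complex
    and then averaged."""
    config = config or ECGConfig()
    n = config.n_complexes
    r_times = detect_r_peaks(signal, config)
    if r_times.size < n + 1:
        raise AnalysisError(
            f"record has {r_times.size} detected beats; need at least {n + 1}")

    # the run must be followed by one more detected beat so the last RR exists
    scores, threshold = _artefact_scores(signal, r_times, config)
    clean = scores < threshold
    clean[-1] = False  # cannot start-or-extend a usable run at the final beat
    candidates = [i for i in range(r_times.size - n)
                  if clean[i:i + n].all()]
    if not candidates:
        raise AnalysisError(
            f"no run of {n} consecutive clean complexes; longest clean run "
            f"found: {_longest_run(clean)}")

    fids = None
    start = None
    last_err: FiducialError | None = None
    for cand in candidates:
        try:
            rr_local = np.diff(r_times[cand:cand + n + 1]) * 1e3
            fids = [delineate_complex(signal, r_times[cand + k], rr_local[k], config)
                    for k in range(n)]
            start = cand
            break
        except FiducialError as err:
            last_err = err
            continue
    if fids is None:
        raise AnalysisError(f"delineation failed on every clean run: {last_err}")

    table = measure_intervals(fids, next_r_time=r_times[start + n])
    table["qtc_mitchell_ms"] = qtc_mitchell(table["qt_ms"].to_numpy(),
                                            table["rr_ms"].to_numpy())
    table["qtc_mccauley_ms"] = qtc_mccauley(table["qt_ms"].to_numpy(),
                                            table["rr_ms"].to_numpy())
    return ECGSummary(
        rr_ms=float(table["rr_ms"].mean()),
        hr_bpm=float(table["hr_bpm"].mean()),
        pr_ms=float(table["pr_ms"].mean()) if table["pr_ms"].notna().any() else float("nan"),
        qrs_ms=float(table["qrs_ms"].mean()),
        qt_ms=float(table["qt_ms"].mean()),
        qtc_mitchell_ms=float(table["qtc_mitchell_ms"].mean()),
        qtc_mccauley_ms=float(table["qtc_mccauley_ms"].mean()),
        j_wave_mv=float(table["j_wave_mv"].mean()) if table["j_wave_mv"].notna().any() else float("nan"),
        n_complexes=n,
        first_beat_index=int(start),
        per_beat=table,
    )
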