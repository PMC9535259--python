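"""Ventricular action-potential feature extraction and repolarization
variability.

Current-clamp trains (APs evoked at 1 s intervals by 3 ms current pulses)
are segmented into per-stimulus windows; each captured AP yields:

* resting potential: mean over the 40 ms ending 2 ms before the stimulus;
* overshoot: maximum potential; amplitude = overshoot - resting potential;
* V_max: maximum of a 5-point Savitzky-Golay smoothed derivative on the
  upstroke (the first 0.5 ms after the stimulus is masked from the search,
  but not from the peak search);
* APD_x: time from the overshoot peak to the first sustained downward
  crossing of the level ``overshoot - x/100 * amplitude``, with linear
  interpolation between samples.  Crossings are searched sequentially
  (APD_10 before APD_25 before ...) which enforces APD monotonicity by
  construction.  Late-repolarization levels are located on a more heavily
  smoothed copy of the trace: the terminal phase of the murine AP decays
  slowly, so the crossing is shallow and noise-limited.
* triangulation = APD_90 - APD_25.

Beat-to-beat variability of repolarization (BVR, a Poincare-derived
short-term variability statistic) over n consecutive APD_90 values:

    BVR = sum |APD90_{i+1} - APD90_i| / (n_pairs * sqrt(2)),

with pairs containing a missing APD_90 excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal as sig

from .errors import AnalysisError, PairingError, ValidationError
from .signal import SampledSignal
from .stats import TestResult, mean_sem, ttest_paired

__all__ = [
    "APProtocol",
    "APConfig",
    "APWindow",
    "APFeatures",
    "BVRResult",
    "segment_aps",
    "extract_ap_features",
    "compute_bvr",
    "drug_effect",
]

APD_FRACTIONS = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class APProtocol:
    """Stimulation protocol metadata."""

    stimulation_interval: float = 1.0   # s
    pulse_duration: float = 3.0         # ms
    threshold_stimulus: float = float("nan")  # pA, experimental metadata only

    def __post_init__(self) -> None:
        if self.stimulation_interval <= 0 or self.pulse_duration <= 0:
            raise ValidationError("protocol durations must be positive")


@dataclass
class APConfig:
    """Tunables of AP feature extraction."""

    rmp_window_ms: tuple[float, float] = (42.0, 2.0)  # before the stimulus
    vmax_mask_ms: float = 0.5            # post-stimulus mask for the V_max search
    peak_smooth_ms: float = 0.3
    capture_level_mv: float = 0.0        # an AP must cross this to count
    onset_detect_slope_v_per_s: float = 10.0
    # smoothing used when locating APD level crossings, by repolarized fraction
    apd_smooth_ms: tuple[tuple[float, float], ...] = (
        (50.0, 1.0), (75.0, 5.0), (100.0, 15.0))
    sustain_ms: float = 0.3              # crossing must hold below level this long
    refine_from_fraction: float = 60.0   # LS-refine crossings of later levels
    refine_half_window_ms: float = 30.0
    exp_refine_from_fraction: float = 85.0  # exponential-tail fit for the end
    apd_fractions: tuple[int, ...] = APD_FRACTIONS
    bvr_min_aps: int = 2
    bvr_max_aps: int = 15


@dataclass
class APWindow:
    """One per-stimulus analysis window."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float       # absolute time of the first sample (s)
    stimulus_time: float    # absolute stimulus time (s)
    index: int
    captured: bool


@dataclass
class APFeatures:
    resting_potential: float   # mV
    overshoot: float           # mV
    amplitude: float           # mV
    v_max: float               # V/s
    apd: dict = field(default_factory=dict)   # fraction -> ms (NaN if missing)
    triangulation: float = float("nan")       # APD90 - APD25, ms
    peak_time: float = float("nan")           # absolute s
    index: int = -1

    @property
    def apd10(self) -> float: return self.apd.get(10, float("nan"))
    @property
    def apd25(self) -> float: return self.apd.get(25, float("nan"))
    @property
    def apd50(self) -> float: return self.apd.get(50, float("nan"))
    @property
    def apd75(self) -> float: return self.apd.get(75, float("nan"))
    @property
    def apd90(self) -> float: return self.apd.get(90, float("nan"))


@dataclass
class BVRResult:
    bvr: float                     # ms
    n_aps: int
    apd90_series: np.ndarray       # ms
    poincare_pairs: np.ndarray     # (n_pairs, 2): (APD90_n, APD90_n+1)


# ------------------------------------------------------------- segmentation

def _detect_stimulus_times(trace: SampledSignal, protocol: APProtocol,
                           config: APConfig) -> np.ndarray:
    """Locate stimuli from upstroke onsets when no protocol times are given.

    The onset of each upstroke is the time at which the smoothed derivative
    first exceeds ``onset_detect_slope_v_per_s`` walking back from the
    maximal-slope point.
    """
    fs = trace.sampling_rate
    v = sig.savgol_filter(trace.samples, 5, 2, deriv=1) * fs / 1000.0  # V/s
    min_gap = max(int(0.5 * protocol.stimulation_interval * fs), 1)
    height = max(config.onset_detect_slope_v_per_s * 3.0, 0.2 * v.max())
    peaks, _ = sig.find_peaks(v, height=height, distance=min_gap)
    if peaks.size < 2:
        raise AnalysisError("fewer than 2 upstrokes detected in the AP train")
    onsets = []
    for p in peaks:
        i = p
        while i > 0 and v[i] > config.onset_detect_slope_v_per_s:
            i -= 1
        onsets.append(trace.start_time + i / fs)
    return np.asarray(onsets)


def segment_aps(trace: SampledSignal, protocol: APProtocol,
                stimulus_times: Sequence[float] | None = None,
                config: APConfig | None = None) -> list[APWindow]:
    """One window per stimulus, from 50 ms pre-stimulus to the next stimulus.

    Windows whose potential never crosses ``capture_level_mv`` (default
    0 mV) are flagged non-captured and excluded from feature extraction.
    """
    config = config or APConfig()
    if stimulus_times is None:
        stim = _detect_stimulus_times(trace, protocol, config)
    else:
        stim = np.asarray(stimulus_times, dtype=float)
    if stim.size < 2:
        raise AnalysisError("segment_aps requires >= 2 stimuli")
    fs = trace.sampling_rate
    windows: list[APWindow] = []
    for k, s in enumerate(stim):
        t0 = max(s - 0.05, trace.start_time)
        t1 = stim[k + 1] if k + 1 < stim.size else min(
            s + protocol.stimulation_interval, trace.end_time)
        i0, i1 = trace.index_at(t0), trace.index_at(t1)
        if i1 - i0 < int(0.1 * fs):
            continue
        seg = trace.samples[i0:i1]
        captured = bool(np.max(seg) > config.capture_level_mv)
        windows.append(APWindow(samples=seg, sampling_rate=fs,
                                start_time=trace.start_time + i0 / fs,
                                stimulus_time=s, index=k, captured=captured))
    return windows


# ---------------------------------------------------------------- features

def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    n = max(int(n), 1)
    if n == 1:
        return x
    return np.convolve(x, np.ones(n) / n, mode="same")


def _sustained_crossing(y: np.ndarray, start: int, level: float, hold: int
                        ) -> float | None:
    """Fractional index of the first above-to-below crossing of ``level``
    after ``start`` that stays below for ``hold`` samples."""
    below = y[start:] < level
    if not below.any():
        return None
    # an upstroke smeared by smoothing can sit below the level at the very
    # start of the search; a crossing must be a transition from above
    trans = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    for i in trans:
        if np.all(below[i:min(i + hold, below.size)]):
            gi = start + i
            frac = (y[gi - 1] - level) / (y[gi - 1] - y[gi])
            return gi - 1 + frac
    return None


def _refine_crossing(x: np.ndarray, prelim: float, level: float,
                     half: int, lo: int, band: float = np.inf) -> float:
    """Refine a level-crossing estimate by a local quadratic least-squares
    fit of the raw trace around the preliminary crossing.

    The terminal repolarization slope is shallow, so a first-crossing
    estimate on a smoothed trace is noise-limited; fitting a quadratic over
    a window around it uses every local sample while tracking the decay's
    curvature (a straight-line fit would be biased on an exponential).
    The window is clipped where the trace leaves ``level +/- band`` so the
    fit never spans a distant morphological feature.
    """
    c = int(round(prelim))
    if np.isfinite(band):
        right = np.flatnonzero(x[c:min(c + half, x.size)] < level - band)
        if right.size:
            half = min(half, int(right[0]))
        left = np.flatnonzero(x[max(c - half, 0):c][::-1] > level + band)
        if left.size:
            half = min(half, int(left[0]))
    i0 = max(c - half, lo)
    i1 = min(c + half, x.size - 1)
    if i1 - i0 < 8:
        return prelim
    t = np.arange(i0, i1 + 1, dtype=float) - prelim
    coef = np.polyfit(t, x[i0:i1 + 1], 2)
    roots = np.roots([coef[0], coef[1], coef[2] - level])
    real = roots[np.abs(roots.imag) < 1e-9].real
    if real.size == 0:
        return prelim
    return prelim + float(real[np.argmin(np.abs(real))])


def _refine_crossing_exp(x: np.ndarray, prelim: float, level: float,
                         lo: int, band: float = np.inf) -> float:
    """Final refinement of a terminal-repolarization crossing with a local
    exponential-decay fit ``c + A exp(-t/tau)``.

    The late murine AP decays mono-exponentially on this scale, so the fit
    uses a wide window (0.4 x the provisional APD on either side, which
    stays clear of the fast early phase and of the final return to rest)
    and solves the fitted curve for the level analytically.  Falls back to
    ``prelim`` whenever the fit fails or wanders.
    """
    from scipy.optimize import curve_fit

    c0 = int(round(prelim))
    half = int(0.4 * (c0 - lo))
    if np.isfinite(band):
        right = np.flatnonzero(x[c0:min(c0 + half, x.size)] < level - band)
        if right.size:
            half = min(half, int(right[0]))
        left = np.flatnonzero(x[max(c0 - half, 0):c0][::-1] > level + band)
        if left.size:
            half = min(half, int(left[0]))
    i0, i1 = max(c0 - half, lo), min(c0 + half, x.size - 1)
    if i1 - i0 < 50:
        return prelim
    t = np.arange(i0, i1 + 1, dtype=float) - prelim
    y = x[i0:i1 + 1]
    rest0 = float(np.median(y[-max((i1 - i0) // 10, 5):]))
    tau0 = max(float(c0 - lo) * 0.6, 10.0)
    a0 = max(float(level) - rest0, 1e-3)

    def model(tt, c, a, tau):
        return c + a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=(rest0, a0, tau0), maxfev=2000)
        c, a, tau = popt
        arg = (level - c) / a
        if a <= 0 or tau <= 0 or arg <= 0:
            return prelim
        shift = -tau * math.log(arg)
        if abs(shift) > half / 2:
            return prelim
        return prelim + shift
    except Exception:
        return prelim


def extract_ap_features(window: APWindow, config: APConfig | None = None
                        ) -> APFeatures:
    """Morphology of one captured AP window."""
    config = config or APConfig()
    if not window.captured:
        raise AnalysisError("cannot extract features from a non-captured window")
    fs = window.sampling_rate
    dt_ms = 1000.0 / fs
    x = window.samples
    stim_i = int(round((window.stimulus_time - window.start_time) * fs))

    w0 = stim_i - int(config.rmp_window_ms[0] * 1e-3 * fs)
    w1 = stim_i - int(config.rmp_window_ms[1] * 1e-3 * fs)
    if w0 < 0 or w1 <= w0:
        raise AnalysisError("pre-stimulus window does not fit in the AP window")
    rmp = float(np.mean(x[w0:w1]))

    # overshoot peak: lightly smoothed argmax, then a local parabola fit on
    # the raw trace (the peak is the APD clock zero, so its time and value
    # must not be noise-limited)
    xs_peak = _moving_average(x, int(config.peak_smooth_ms * 1e-3 * fs))
    peak_i = stim_i + int(np.argmax(xs_peak[stim_i:]))
    peak_f = float(peak_i)
    overshoot = float(xs_peak[peak_i])
    # local cubic fit around the rounded maximum: the cubic term absorbs
    # the mild upstroke/decay asymmetry so the stationary value is an
    # unbiased low-noise overshoot estimate
    half = int(1.0e-3 * fs)
    i0, i1 = max(peak_i - half, stim_i), min(peak_i + half, x.size - 1)
    if i1 - i0 >= 10:
        tt = np.arange(i0, i1 + 1, dtype=float) - peak_i
        coef = np.polyfit(tt, x[i0:i1 + 1], 4)
        der = np.polyder(coef)
        roots = np.roots(der)
        roots = roots[np.abs(roots.imag) < 1e-9].real
        # accept only an interior local maximum of the fitted cubic
        curv = np.polyval(np.polyder(der), roots)
        roots = roots[(np.abs(roots) <= 0.7 * half) & (curv < 0)]
        if roots.size:
            j = int(np.argmin(np.abs(roots)))
            peak_f = peak_i + float(roots[j])
            overshoot = float(np.polyval(coef, roots[j]))
    amplitude = overshoot - rmp
    if amplitude <= 0:
        raise AnalysisError("non-positive AP amplitude")

    # V_max from the 5-point smoothed derivative, stimulus(+mask) -> peak
    dv = sig.savgol_filter(x, 5, 2, deriv=1) * fs / 1000.0  # V/s
    m0 = stim_i + int(config.vmax_mask_ms * 1e-3 * fs)
    v_max = float(np.max(dv[m0:peak_i + 1])) if peak_i > m0 else float("nan")

    # APD levels, searched sequentially with fraction-dependent smoothing
    smooth_cache: dict[int, np.ndarray] = {}

    def smoothed_for(frac: float) -> np.ndarray:
        for upto, ms in config.apd_smooth_ms:
            if frac <= upto:
                n = int(ms * 1e-3 * fs)
                break
        else:
            n = int(config.apd_smooth_ms[-1][1] * 1e-3 * fs)
        if n not in smooth_cache:
            smooth_cache[n] = _moving_average(x, n)
        return smooth_cache[n]

    hold = max(int(config.sustain_ms * 1e-3 * fs), 1)
    apd: dict[int, float] = {}
    search_start = peak_i
    for frac in sorted(config.apd_fractions):
        level = overshoot - frac / 100.0 * amplitude
        y = smoothed_for(frac)
        cross = _sustained_crossing(y, search_start, level, hold)
        if cross is None:
            apd[frac] = float("nan")
        else:
            if frac >= config.refine_from_fraction:
                # window scales with the provisional APD: late murine
                # repolarization is slow, so more samples buy precision,
                # but the window must stay small against the decay scale
                half_ms = min(0.35 * (cross - peak_f) * dt_ms,
                              1.5 * config.refine_half_window_ms)
                half_ms = max(half_ms, 2.0)
                cross = _refine_crossing(x, cross, level,
                                         int(half_ms * 1e-3 * fs), lo=peak_i,
                                         band=0.12 * amplitude)
                if frac >= config.exp_refine_from_fraction:
                    cross = _refine_crossing_exp(x, cross, level, lo=peak_i,
                                                 band=0.08 * amplitude)
            apd[frac] = (cross - peak_f) * dt_ms
            search_start = int(math.floor(cross))

    tri = apd.get(90, float("nan")) - apd.get(25, float("nan"))
    return APFeatures(resting_potential=rmp, overshoot=overshoot,
                      amplitude=amplitude, v_max=v_max, apd=apd,
                      triangulation=tri,
                      peak_time=window.start_time + peak_i / fs,
                      index=window.index)


def features_frame(features: Sequence[APFeatures]) -> pd.DataFrame:
    """Tidy per-AP table from a sequence of :class:`APFeatures`."""
    rows = []
    for f in features:
        row = {"ap_index": f.index, "resting_potential_mv": f.resting_potential,
               "overshoot_mv": f.overshoot, "amplitude_mv": f.amplitude,
               "v_max_v_per_s": f.v_max, "triangulation_ms": f.triangulation}
        for frac, val in f.apd.items():
            row[f"apd{frac}_ms"] = val
        rows.append(row)
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- BVR

def compute_bvr(apd90_series, max_aps: int | None = None) -> BVRResult:
    """Beat-to-beat variability of repolarization over consecutive APD_90.

    ``bvr = sum |APD90_{i+1} - APD90_i| / (n_pairs * sqrt(2))`` where pairs
    with a missing member are excluded.  ``max_aps`` clamps the series to
    its first values (the measurement convention is 10-15 consecutive APs).
    """
    series = np.asarray(apd90_series, dtype=float).ravel()
    if max_aps is not None:
        series = series[:max_aps]
    a, b = series[:-1], series[1:]
    valid = ~(np.isnan(a) | np.isnan(b))
    if valid.sum() < 1 or series[~np.isnan(series)].size < 2:
        raise AnalysisError("compute_bvr requires >= 2 consecutive APD90 values")
    diffs = np.abs(b[valid] - a[valid])
    bvr = float(diffs.sum() / (diffs.size * math.sqrt(2.0)))
    pairs = np.column_stack([a[valid], b[valid]])
    return BVRResult(bvr=bvr, n_aps=int(series[~np.isnan(series)].size),
                     apd90_series=series, poincare_pairs=pairs)


# ------------------------------------------------------------- drug effect

def drug_effect(pre: pd.DataFrame, post: pd.DataFrame,
                cell_column: str = "cell_id") -> dict:
    """Paired pre/post drug comparison across cells.

    ``pre`` and ``post`` are per-cell feature tables (one row per cell) that
    must share ``cell_column`` values.  Returns per-cell percentage change
    in APD_90 (100 * (post - pre) / pre), absolute change in triangulation,
    and paired t-tests across cells.
    """
    if cell_column not in pre.columns or cell_column not in post.columns:
        raise PairingError(f"both tables need a {cell_column!r} column")
    merged = pre.merge(post, on=cell_column, suffixes=("_pre", "_post"))
    if len(merged) != len(pre) or len(merged) != len(post):
        raise PairingError("pre and post tables do not pair one-to-one by cell")
    out = pd.DataFrame({cell_column: merged[cell_column]})
    out["apd90_pct_change"] = 100.0 * (
        merged["apd90_ms_post"] - merged["apd90_ms_pre"]) / merged["apd90_ms_pre"]
    out["triangulation_change_ms"] = (
        merged["triangulation_ms_post"] - merged["triangulation_ms_pre"])
    tests = {
        "apd90": ttest_paired(merged["apd90_ms_pre"], merged["apd90_ms_post"]),
        "triangulation": ttest_paired(merged["triangulation_ms_pre"],
                                      merged["triangulation_ms_post"]),
    }
    return {
        "per_cell": out,
        "tests": tests,
        "apd90_pct_change": mean_sem(out["apd90_pct_change"], "apd90 % change"),
        "triangulation_change_ms": mean_sem(out["triangulation_change_ms"],
                                            "triangulation change"),
    }
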