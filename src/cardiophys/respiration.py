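"""Whole-body plethysmography: breath segmentation and apnoea detection.

Breaths are delimited by zero crossings of the mean-centred, smoothed flow
(20 ms moving average by default).  By the default convention expiration is
the positive flow lobe; chambers wired the other way round are handled by
the ``polarity`` flag.  Lobes whose area falls below a hysteresis floor are
merged into their neighbour so noise wiggles do not split breaths.

Apnoea rule: a running average of the expiration time is maintained on a
one-minute cadence (a trailing 60 s window recomputed at 60 s ticks and
held constant in between; a continuously sliding variant is available).
A breath whose expiration time is strictly longer than ``apnoea_factor``
(default 4) times this running average is an apnoea.  Detection is
restricted to the analysis window (default one hour) that follows the
adaptation period (default 20 min), and never reports events from the
first minute, where the average is still undefined.  The rule is purely
ratio-based, so the analysis is independent of flow units and of uniform
time-scaling of the breathing pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .signal import SampledSignal

__all__ = [
    "RespConfig",
    "ApnoeaEvent",
    "ApnoeaSummary",
    "segment_breaths",
    "running_expiration_average",
    "detect_apnoeas",
    "summarize_apnoeas",
    "analyze_respiration",
]


@dataclass
class RespConfig:
    smooth_ms: float = 20.0
    polarity: str = "pos"            # which flow lobe is expiration
    hysteresis_fraction: float = 0.05  # of the median |lobe area|
    apnoea_factor: float = 4.0
    adaptation_s: float = 1200.0
    window_s: float = 3600.0
    tick_s: float = 60.0
    sliding_average: bool = False    # continuously sliding 60 s window instead


@dataclass(frozen=True)
class ApnoeaEvent:
    breath_index: int
    time: float                # expiration start (s)
    length: float              # s
    baseline_at_event: float   # s


@dataclass(frozen=True)
class ApnoeaSummary:
    apnoea_count: int
    mean_apnoea_length: float  # s; NaN when count == 0
    analysis_window: float     # s
    adaptation_period: float   # s


def _zero_crossings(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linearly interpolated times of sign changes of ``y``."""
    s = np.sign(y)
    s[s == 0] = 1
    idx = np.flatnonzero(s[:-1] != s[1:])
    frac = y[idx] / (y[idx] - y[idx + 1])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def segment_breaths(flow: SampledSignal, config: RespConfig | None = None
                    ) -> pd.DataFrame:
    """Per-breath table with inspiration/expiration boundaries and times."""
    config = config or RespConfig()
    if flow.duration < 60.0:
        raise AnalysisError("respiratory analysis requires >= 60 s of flow")
    if config.polarity not in ("pos", "neg"):
        raise ValidationError("polarity must be 'pos' or 'neg'")
    x = flow.samples - float(np.mean(flow.samples))
    if config.polarity == "neg":
        x = -x
    n = max(int(config.smooth_ms * 1e-3 * flow.sampling_rate), 1)
    if n > 1:
        x = np.convolve(x, np.ones(n) / n, mode="same")
    t = flow.times()

    crossings = _zero_crossings(x, t)
    if crossings.size < 2:
        raise AnalysisError("no zero crossings found in the flow trace")

    # lobes between consecutive crossings, with their signed areas
    dt = flow.dt
    cum = np.concatenate([[0.0], np.cumsum(x) * dt])
    cidx = np.searchsorted(t, crossings)
    starts = np.concatenate([[t[0]], crossings])
    ends = np.concatenate([crossings, [t[-1]]])
    bidx = np.concatenate([[0], cidx, [x.size]])
    areas = np.diff(cum[bidx])
    mids = 0.5 * (starts + ends)
    mid_idx = np.clip(np.searchsorted(t, mids), 0, x.size - 1)
    signs = np.sign(x[mid_idx])

    # hysteresis: merge low-area lobes into the previous lobe
    floor = config.hysteresis_fraction * float(np.median(np.abs(areas)))
    lobes: list[list] = []   # [sign, start, end, area]
    for s0, e0, a0, sg in zip(starts, ends, areas, signs):
        if lobes and (abs(a0) < floor or sg == lobes[-1][0]):
            lobes[-1][2] = e0
            lobes[-1][3] += a0
        else:
            lobes.append([sg, s0, e0, a0])
    # a merge can leave adjacent lobes with equal signs; coalesce
    merged: list[list] = []
    for lb in lobes:
        if merged and merged[-1][0] == lb[0]:
            merged[-1][2] = lb[2]
            merged[-1][3] += lb[3]
        else:
            merged.append(lb)

    rows = []
    k = 0
    i = 0
    while i + 1 < len(merged):
        neg, pos = merged[i], merged[i + 1]
        if neg[0] < 0 and pos[0] > 0:
            rows.append({
                "breath_index": k,
                "inspiration_start": neg[1],
                "expiration_start": pos[1],
                "expiration_end": pos[2],
                "expiration_time": pos[2] - pos[1],
            })
            k += 1
            i += 2
        else:
            i += 1
    if not rows:
        raise AnalysisError("no complete breaths segmented from the flow trace")
    return pd.DataFrame(rows)


def running_expiration_average(breaths: pd.DataFrame,
                               config: RespConfig | None = None) -> np.ndarray:
    """Per-breath expiration-time baseline (s).

    Tick mode (default): recomputed at 60 s ticks as the mean expiration
    time of breaths ending in the trailing 60 s, held constant between
    ticks; an empty window carries the last defined value forward; NaN
    during the first minute.  Sliding mode: trailing 60 s window ending at
    each breath's expiration start, excluding the breath under test.
    """
    config = config or RespConfig()
    te = breaths["expiration_time"].to_numpy(dtype=float)
    t_end = breaths["expiration_end"].to_numpy(dtype=float)
    t_start = breaths["expiration_start"].to_numpy(dtype=float)
    w = config.tick_s

    if config.sliding_average:
        out = np.full(te.size, np.nan)
        last = np.nan
        for i in range(te.size):
            in_win = (t_end > t_start[i] - w) & (t_end <= t_start[i]) \
                & (np.arange(te.size) != i)
            if in_win.any():
                last = float(np.mean(te[in_win]))
            if t_start[i] >= w:
                out[i] = last
        return out

    last_tick = int(np.floor(max(t_start.max(), t_end.max()) / w))
    tick_value = np.full(last_tick + 1, np.nan)  # tick_value[k] defined at k*w
    prev = np.nan
    for k in range(1, last_tick + 1):
        in_win = (t_end > (k - 1) * w) & (t_end <= k * w)
        prev = float(np.mean(te[in_win])) if in_win.any() else prev
        tick_value[k] = prev
    ticks = np.clip((t_start // w).astype(int), 0, last_tick)
    out = tick_value[ticks]
    out[ticks < 1] = np.nan
    return out


def detect_apnoeas(breaths: pd.DataFrame, baselines,
                   config: RespConfig | None = None) -> list[ApnoeaEvent]:
    """Breaths whose expiration time is strictly greater than
    ``apnoea_factor`` times the running baseline, within the analysis
    window following the adaptation period."""
    config = config or RespConfig()
    baselines = np.asarray(baselines, dtype=float)
    if baselines.size != len(breaths):
        raise ValidationError("one baseline per breath required")
    t_start = breaths["expiration_start"].to_numpy(dtype=float)
    te = breaths["expiration_time"].to_numpy(dtype=float)
    t0 = config.adaptation_s
    t1 = config.adaptation_s + config.window_s
    events: list[ApnoeaEvent] = []
    for i in range(len(breaths)):
        if not np.isfinite(baselines[i]):
            continue
        if not (t0 <= t_start[i] < t1):
            continue
        if te[i] > config.apnoea_factor * baselines[i]:
            events.append(ApnoeaEvent(
                breath_index=int(breaths["breath_index"].iloc[i]),
                time=float(t_start[i]), length=float(te[i]),
                baseline_at_event=float(baselines[i])))
    return events


def summarize_apnoeas(events: list[ApnoeaEvent],
                      config: RespConfig | None = None) -> ApnoeaSummary:
    config = config or RespConfig()
    count = len(events)
    mean_len = float(np.mean([e.length for e in events])) if count else float("nan")
    return ApnoeaSummary(apnoea_count=count, mean_apnoea_length=mean_len,
                         analysis_window=config.window_s,
                         adaptation_period=config.adaptation_s)


def analyze_respiration(flow: SampledSignal, config: RespConfig | None = None
                        ) -> tuple[pd.DataFrame, np.ndarray, list[ApnoeaEvent],
                                   ApnoeaSummary]:
    """Full chain: segment -> running average -> detect -> summarize."""
    config = config or RespConfig()
    breaths = segment_breaths(flow, config)
    baselines = running_expiration_average(breaths, config)
    events = detect_apnoeas(breaths, baselines, config)
    return breaths, baselines, events, summarize_apnoeas(events, config)
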