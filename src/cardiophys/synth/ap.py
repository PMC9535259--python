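"""Synthetic ventricular AP trains with analytically known per-AP features.

Template construction (per beat, all times from the stimulus):

* rest at the target resting potential until ``latency_ms`` after the
  stimulus (a small passive bump marks sub-threshold stimuli);
* upstroke with a trapezoidal velocity profile — raised-cosine acceleration
  over ``ramp_ms``, a constant plateau at exactly the target V_max, and a
  mirrored deceleration — integrating to exactly the target amplitude, so
  the true maximum upstroke velocity equals the parameter;
* repolarization from the overshoot peak as a two-exponential decay
  ``f(t) = w e^{-t/tau1} + (1-w) e^{-t/tau2}`` (fraction of amplitude still
  to repolarize) whose time constants are solved by root-finding so the
  crossings of the 50% and 90% levels land exactly on the APD50/APD90
  targets measured from the peak.  The two-exponential family is the
  minimal one that decouples APD50 from APD90 (and hence triangulation);
* past 95% repolarization the tail is accelerated (exponential, 25 ms time
  constant) so the membrane is back at rest well before the next stimulus.

Per-beat APD variability perturbs the APD90 target (Gaussian SD
``beat_to_beat_sd``) and re-solves the decay.  Ground-truth APD_x values
are computed by root-finding on the noiseless per-beat template — the same
independent oracle used by the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ..errors import ValidationError
from ..signal import SampledSignal
from ..ap import APProtocol, APD_FRACTIONS

__all__ = ["APGenParams", "generate_ap_train", "solve_repolarization",
           "repol_fraction", "true_apd"]

_TAIL_SWITCH = 0.05     # accelerate the decay past 95% repolarization
_TAIL_TAU_MS = 25.0
#: peak-rounding constant (ms) of the repolarization time warp
#: g(t) = t^2 / (t + c): zero slope at the peak, asymptotically the identity,
#: so the overshoot is a smooth (measurable) maximum rather than a corner
_PEAK_ROUND_MS = 6.0


def _warp(t_ms, c: float = _PEAK_ROUND_MS):
    t = np.asarray(t_ms, dtype=float)
    return t * t / (t + c)


def _unwarp(u: float, c: float = _PEAK_ROUND_MS) -> float:
    """Inverse of :func:`_warp`: t such that t^2/(t+c) = u (u >= 0)."""
    return 0.5 * (u + math.sqrt(u * u + 4.0 * u * c))


@dataclass
class APGenParams:
    """Generator parameters; defaults follow adult female mouse ventricular
    myocytes at 1 Hz stimulation, 35-37 C."""

    rmp: float = -72.8              # mV
    overshoot: float = 43.6         # mV
    v_max_target: float = 150.1     # V/s
    apd50_target: float = 5.2       # ms from the overshoot peak
    apd90_target: float = 112.6     # ms from the overshoot peak
    beat_to_beat_sd: float = 0.0    # ms, Gaussian perturbation of APD90
    n_aps: int = 12
    stimulation_interval: float = 1.0  # s
    pulse_duration: float = 3.0        # ms
    threshold_stimulus: float = 707.3  # pA, metadata only
    latency_ms: float = 0.5
    ramp_ms: float = 0.1
    noise_sd: float = 0.5           # mV
    sampling_rate: float = 10000.0
    seed: int | None = None
    skipped_beats: tuple = ()       # indices of sub-threshold stimuli

    def validate(self) -> None:
        if self.rmp >= self.overshoot:
            raise ValidationError("rmp must be below overshoot")
        if not (0 < self.apd50_target < self.apd90_target):
            raise ValidationError("require 0 < apd50 < apd90")
        if self.apd90_target >= self.stimulation_interval * 1000.0 * 0.6:
            raise ValidationError("apd90 too long for the stimulation interval")
        if self.v_max_target <= 0 or self.n_aps < 1:
            raise ValidationError("v_max_target and n_aps must be positive")
        amp = self.overshoot - self.rmp
        if self.v_max_target * self.ramp_ms >= amp:
            raise ValidationError("upstroke cannot integrate to the amplitude")


def repol_fraction(t_ms, w: float, tau1: float, tau2: float):
    """Fraction of the amplitude still to repolarize, t ms after the peak."""
    t = np.asarray(t_ms, dtype=float)
    return w * np.exp(-t / tau1) + (1.0 - w) * np.exp(-t / tau2)


def solve_repolarization(apd50: float, apd90: float
                         ) -> tuple[float, float, float]:
    """Solve ``(w, tau1, tau2)`` so the 50% / 90% crossings hit the targets.

    The fast-phase weight ``w`` starts at 0.5 — an even split places the
    late decay's 90% crossing on its steepest attainable course while still
    giving the murine AP its characteristic fast early repolarization — and
    is raised automatically for target pairs the even split cannot reach.
    When the constraint equation has two roots in the slow time constant the
    larger one (slowest physiological tail) is taken.
    """
    apd50, apd90 = float(apd50), float(apd90)
    if not 0 < apd50 < apd90:
        raise ValidationError("require 0 < apd50 < apd90")

    def try_w(w: float) -> tuple[float, float] | None:
        def tau1_of(tau2: float) -> float:
            rem = 0.5 - (1.0 - w) * math.exp(-apd50 / tau2)
            if not 0.0 < rem < w:
                return math.nan
            return -apd50 / math.log(rem / w)

        def g(tau2: float) -> float:
            tau1 = tau1_of(tau2)
            if math.isnan(tau1):
                return math.nan
            return (w * math.exp(-apd90 / tau1)
                    + (1.0 - w) * math.exp(-apd90 / tau2) - 0.1)

        grid = np.geomspace(apd50 * 1e-2, apd90 * 1e3, 200)
        vals = np.array([g(tau) for tau in grid])
        ok = ~np.isnan(vals)
        grid, vals = grid[ok], vals[ok]
        sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
        if sign_change.size == 0:
            return None
        i = sign_change[-1]   # largest-tau2 root
        tau2 = brentq(g, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14)
        return tau1_of(tau2), tau2

    for w in (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99):
        sol = try_w(w)
        if sol is not None and not math.isnan(sol[0]):
            return w, sol[0], sol[1]
    raise ValidationError(
        f"no two-exponential decay reaches APD50={apd50}, APD90={apd90}")


def true_apd(fraction: float, w: float, tau1: float, tau2: float) -> float:
    """Time (ms from the peak) at which repolarization reaches ``fraction`` %."""
    level = 1.0 - fraction / 100.0
    f = lambda t: repol_fraction(t, w, tau1, tau2) - level
    hi = 10.0 * max(tau1, tau2)
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def _upstroke(tau_ms: np.ndarray, vmax: float, ramp: float, plateau: float,
              v_edge: float, cap: float) -> np.ndarray:
    """Integrated upstroke (mV above rest); vmax in mV/ms, times in ms.

    Velocity profile: raised-cosine 0 -> vmax over ``ramp``; constant vmax
    over ``plateau``; raised-cosine vmax -> ``v_edge`` over ``ramp``; then a
    parabolic peak cap of duration ``cap`` whose slope falls linearly from
    ``v_edge`` to zero.  The cap's curvature is matched by the caller to the
    early decay's, so the synthetic peak is a locally symmetric quadratic
    maximum (a measurable overshoot, as in a real rounded AP peak).
    """
    y = np.empty_like(tau_ms)
    r, L, h = ramp, plateau, cap
    a1 = 0.5 * vmax * r                 # area of the acceleration ramp
    a2 = vmax * L
    a3 = 0.5 * (vmax + v_edge) * r      # deceleration ramp area
    m = tau_ms < 0
    y[m] = 0.0
    m = (tau_ms >= 0) & (tau_ms < r)
    y[m] = 0.5 * vmax * (tau_ms[m] - (r / math.pi) * np.sin(math.pi * tau_ms[m] / r))
    m = (tau_ms >= r) & (tau_ms < r + L)
    y[m] = a1 + vmax * (tau_ms[m] - r)
    m = (tau_ms >= r + L) & (tau_ms < 2 * r + L)
    u = tau_ms[m] - r - L
    y[m] = a1 + a2 + 0.5 * (vmax + v_edge) * u + 0.5 * (vmax - v_edge) * \
        (r / math.pi) * np.sin(math.pi * u / r)
    m = tau_ms >= 2 * r + L
    u = np.minimum(tau_ms[m] - 2 * r - L, h)
    kappa = v_edge / h if h > 0 else 0.0
    y[m] = a1 + a2 + a3 + v_edge * u - 0.5 * kappa * u ** 2
    return y


def generate_ap_train(params: APGenParams
                      ) -> tuple[SampledSignal, pd.DataFrame, APProtocol,
                                 np.ndarray]:
    """Synthesize a stimulated AP train.

    Returns ``(signal, truth, protocol, stimulus_times)``.  Truth has one
    row per stimulus with the analytic per-beat features (NaN for skipped,
    sub-threshold stimuli) including ``apd10 ... apd90``, ``triangulation``,
    ``v_max``, ``rmp``, ``overshoot``, ``amplitude`` and ``captured``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    dt_ms = 1000.0 / fs
    interval = params.stimulation_interval
    first = 0.25
    stim_times = first + interval * np.arange(params.n_aps)
    total = stim_times[-1] + interval
    n = int(round(total * fs)) + 1
    x = np.full(n, params.rmp)

    amp = params.overshoot - params.rmp
    vmax = params.v_max_target  # V/s == mV/ms
    ramp = params.ramp_ms

    apd90_targets = params.apd90_target + params.beat_to_beat_sd * \
        rng.standard_normal(params.n_aps)
    apd90_targets = np.maximum(apd90_targets, 6.5 * params.apd50_target)

    rows = []
    skipped = set(int(i) for i in params.skipped_beats)
    for k, s in enumerate(stim_times):
        i0 = int(round(s * fs))
        i1 = min(int(round((s + interval) * fs)), n)
        t_ms = (np.arange(i0, i1) - i0) * dt_ms  # ms since stimulus
        if k in skipped:
            # passive sub-threshold response: small charging bump
            bump = 6.0 * (1 - np.exp(-np.clip(t_ms, 0, params.pulse_duration)
                                     / 1.2)) * np.exp(
                -np.maximum(t_ms - params.pulse_duration, 0.0) / 4.0)
            x[i0:i1] = params.rmp + bump
            rows.append({"ap_index": k, "stim_time": s, "captured": False,
                         "rmp": params.rmp, "overshoot": float("nan"),
                         "amplitude": float("nan"), "v_max": float("nan"),
                         "triangulation": float("nan"),
                         **{f"apd{f}": float("nan") for f in APD_FRACTIONS}})
            continue

        # the decay runs in warped time so the peak is a smooth maximum
        w, tau1, tau2 = solve_repolarization(
            _warp(params.apd50_target), _warp(float(apd90_targets[k])))
        # peak cap curvature matched to the early decay's so the maximum is
        # locally symmetric; the cap shrinks if the upstroke budget is tight
        kappa = 2.0 * amp * (w / tau1 + (1 - w) / tau2) / _PEAK_ROUND_MS
        h = max(min(1.3, 0.45 * vmax / kappa), 0.02)
        while True:
            v_edge = kappa * h
            plateau = (amp - 0.5 * v_edge * h - 0.5 * vmax * ramp
                       - 0.5 * (vmax + v_edge) * ramp) / vmax
            if plateau >= 0.5 or h <= 0.025:
                break
            h = max(h * 0.8, 0.02)
        if plateau < 0.0:
            raise ValidationError("upstroke cannot integrate to the amplitude")
        peak_off_ms = params.latency_ms + 2 * ramp + plateau + h
        up_tau = t_ms - params.latency_ms
        v = params.rmp + _upstroke(up_tau, vmax, ramp, plateau, v_edge, h)
        rep_tau = t_ms - peak_off_ms
        m = rep_tau > 0
        frac = repol_fraction(_warp(rep_tau[m]), w, tau1, tau2)
        t95 = _unwarp(true_apd(100 * (1 - _TAIL_SWITCH), w, tau1, tau2))
        late = rep_tau[m] > t95
        frac[late] = _TAIL_SWITCH * np.exp(-(rep_tau[m][late] - t95) / _TAIL_TAU_MS)
        v[m] = params.rmp + amp * frac
        x[i0:i1] = v

        apd = {f: _unwarp(true_apd(f, w, tau1, tau2)) for f in APD_FRACTIONS}
        rows.append({"ap_index": k, "stim_time": s, "captured": True,
                     "rmp": params.rmp, "overshoot": params.overshoot,
                     "amplitude": amp, "v_max": vmax,
                     "triangulation": apd[90] - apd[25],
                     **{f"apd{f}": apd[f] for f in APD_FRACTIONS}})

    if params.noise_sd > 0:
        x = x + params.noise_sd * rng.standard_normal(n)

    signal = SampledSignal(samples=x, sampling_rate=fs, start_time=0.0,
                           channel_label="membrane potential (synthetic)",
                           units="mV")
    protocol = APProtocol(stimulation_interval=interval,
                          pulse_duration=params.pulse_duration,
                          threshold_stimulus=params.threshold_stimulus)
    return signal, pd.DataFrame(rows), protocol, stim_times
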