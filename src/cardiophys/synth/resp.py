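"""Synthetic respiratory flow with scheduled apnoeas.

Each breath is an asymmetric pair of half-sine lobes: a negative
inspiration lobe and a positive expiration lobe (the default chamber
convention), with the expiration occupying ``expiration_fraction`` of the
breath period.  A scheduled apnoea stretches one breath's expiration lobe
to ``factor`` times the nominal expiration time, emulating an expiratory
pause.  The truth table lists every breath with its exact lobe boundaries,
so the breath segmenter and the 4x-rule apnoea detector can be validated
event-for-event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ValidationError
from ..signal import SampledSignal

__all__ = ["RespGenParams", "generate_resp_flow"]


@dataclass
class RespGenParams:
    breath_rate: float = 110.0          # breaths per minute
    expiration_fraction: float = 0.55   # of the breath period
    apnoea_schedule: list = field(default_factory=list)  # (time s, factor)
    duration: float = 4800.0            # s
    amplitude: float = 1.0              # arbitrary flow units
    noise_sd: float = 0.01              # flow units
    rate_jitter_cv: float = 0.03        # per-breath period jitter
    sampling_rate: float = 100.0        # Hz
    seed: int | None = None

    def validate(self) -> None:
        if self.breath_rate <= 0:
            raise ValidationError("breath_rate must be positive")
        if not 0.05 < self.expiration_fraction < 0.95:
            raise ValidationError("expiration_fraction must lie in (0.05, 0.95)")
        for t, f in self.apnoea_schedule:
            if f <= 1.0:
                raise ValidationError("apnoea pause factors must exceed 1")
            if not 0 <= t < self.duration:
                raise ValidationError("scheduled apnoea outside the record")
        times = sorted(t for t, _ in self.apnoea_schedule)
        period = 60.0 / self.breath_rate
        max_factor = max((f for _, f in self.apnoea_schedule), default=0.0)
        if any(t2 - t1 < (max_factor + 2.0) * period
               for t1, t2 in zip(times, times[1:])):
            raise ValidationError("scheduled apnoeas overlap")


def generate_resp_flow(params: RespGenParams
                       ) -> tuple[SampledSignal, pd.DataFrame]:
    """Synthesize a flow trace; returns ``(signal, truth)`` where truth has
    one row per breath (``insp_start, exp_start, exp_end, expiration_time,
    is_apnoea, factor``)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    period = 60.0 / params.breath_rate
    te_nominal = params.expiration_fraction * period
    ti_nominal = period - te_nominal

    schedule = sorted(params.apnoea_schedule)
    next_sched = 0

    rows = []
    t_cursor = 0.0
    k = 0
    while t_cursor + period < params.duration:
        jit = 1.0 + params.rate_jitter_cv * rng.standard_normal()
        jit = max(jit, 0.3)
        ti = ti_nominal * jit
        te = te_nominal * jit
        factor = np.nan
        if next_sched < len(schedule) and t_cursor >= schedule[next_sched][0]:
            factor = float(schedule[next_sched][1])
            te = factor * te_nominal
            next_sched += 1
        rows.append({
            "breath_index": k,
            "insp_start": t_cursor,
            "exp_start": t_cursor + ti,
            "exp_end": t_cursor + ti + te,
            "expiration_time": te,
            "is_apnoea": bool(np.isfinite(factor)),
            "factor": factor,
        })
        t_cursor += ti + te
        k += 1
    truth = pd.DataFrame(rows)
    if next_sched < len(schedule):
        raise ValidationError("apnoea schedule extends past the record")

    n = int(round(params.duration * fs)) + 1
    t = np.arange(n) / fs
    x = np.zeros(n)
    for r in rows:
        i0 = int(np.ceil(r["insp_start"] * fs))
        i1 = int(np.ceil(r["exp_start"] * fs))
        i2 = min(int(np.ceil(r["exp_end"] * fs)), n)
        ti = r["exp_start"] - r["insp_start"]
        te = r["expiration_time"]
        # expired volume balances inspired volume, so a long expiratory
        # pause is a shallow slow lobe and the record mean stays at zero
        amp_e = params.amplitude * ti / te
        x[i0:i1] = -params.amplitude * np.sin(
            np.pi * (t[i0:i1] - r["insp_start"]) / ti)
        x[i1:i2] = amp_e * np.sin(
            np.pi * (t[i1:i2] - r["exp_start"]) / te)
    if params.noise_sd > 0:
        x += params.noise_sd * rng.standard_normal(n)

    signal = SampledSignal(samples=x, sampling_rate=fs, start_time=0.0,
                           channel_label="respiratory flow (synthetic)",
                           units="a.u.")
    return signal, truth
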