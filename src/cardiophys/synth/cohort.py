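"""Genotype-labelled synthetic cohorts.

Group-level targets for the wild-type (WT) and heterozygous Mecp2-null
("Mecp2Null+", the female 'Bird'-strain model of Rett syndrome) groups are
published as mean +/- SEM with group sizes; per-animal (or per-cell) true
parameters are drawn from normal distributions with SD reconstructed as
``SEM * sqrt(n)`` — an approximation of the unreported dispersion.  Draws
are lightly truncated so every sampled parameter set satisfies the
generators' structural invariants; truncations are rare and chosen to bind
far from the group means.

Apnoea count and episode-length group values were published only
graphically, so the respiratory schedule distributions here are
package-chosen synthetic values: similar counts in both genotypes, longer
episodes in the Mecp2-null group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ValidationError
from .ecg import ECGGenParams, generate_ecg
from .ap import APGenParams, generate_ap_train
from .resp import RespGenParams, generate_resp_flow

__all__ = [
    "ECG_GROUPS", "AP_GROUPS", "BVR_GROUPS", "RESP_RATE_GROUPS",
    "GS6615_TRIANGULATION", "ecg_preset", "ap_preset", "resp_preset",
    "CohortSpec", "CohortData", "generate_cohort",
]

WT = "WT"
RTT = "Mecp2Null+"

#: ECG group targets: parameter -> (mean, SEM); group n in "n".
ECG_GROUPS = {
    WT: {"rr": (154.4, 8.3), "hr": (399.2, 18.5), "pr": (46.1, 1.2),
         "qrs": (12.3, 0.5), "qt": (53.3, 1.0),
         "qtc_mitchell": (43.2, 0.9), "qtc_mccauley": (58.2, 2.2),
         "j_amp": (0.22, 0.04), "n": 12},
    RTT: {"rr": (134.9, 8.2), "hr": (462.5, 21.4), "pr": (47.4, 2.3),
          "qrs": (11.8, 0.3), "qt": (56.3, 1.4),
          "qtc_mitchell": (48.9, 0.9), "qtc_mccauley": (67.4, 1.8),
          "j_amp": (0.25, 0.03), "n": 15},
}

#: Ventricular AP group targets (per cell): parameter -> (mean, SEM).
AP_GROUPS = {
    WT: {"rmp": (-72.8, 0.8), "overshoot": (43.6, 1.9),
         "amplitude": (116.4, 2.0), "v_max": (150.1, 6.4),
         "apd10": (0.4, 0.0), "apd25": (1.6, 0.2), "apd50": (5.2, 0.7),
         "apd75": (65.5, 7.5), "apd90": (112.6, 9.4),
         "triangulation": (111.0, 9.3), "threshold_stimulus": (707.3, 45.6),
         "n_cells": 24},
    RTT: {"rmp": (-70.0, 1.0), "overshoot": (40.7, 3.1),
          "amplitude": (110.7, 3.6), "v_max": (122.5, 6.7),
          "apd10": (0.6, 0.1), "apd25": (2.2, 0.5), "apd50": (6.8, 1.4),
          "apd75": (94.0, 10.4), "apd90": (151.8, 12.2),
          "triangulation": (149.7, 12.3), "threshold_stimulus": (576.4, 41.1),
          "n_cells": 18},
}

#: Beat-to-beat variability of repolarization: (mean ms, SEM, n cells).
BVR_GROUPS = {WT: (4.1, 0.6, 18), RTT: (5.6, 1.4, 14)}

#: Respiratory rates observed during ECG: (mean bpm, SEM, n).
RESP_RATE_GROUPS = {WT: (106.6, 9.9, 12), RTT: (122.4, 8.9, 15)}

#: Acute GS-6615 (10 uM) effect on AP triangulation (ms): pre -> post, n cells.
GS6615_TRIANGULATION = {RTT: {"pre": 134.1, "post": 110.2, "n": 8},
                        WT: {"pre": 109.0, "post": 90.5, "n": 8}}

#: factor of sqrt(2/pi): BVR of an i.i.d. Gaussian APD90 series with SD sigma
#: converges to sigma*sqrt(2/pi), so presets invert that to pick sigma.
_BVR_TO_SD = float(1.0 / np.sqrt(2.0 / np.pi))

_GENO_ALIASES = {"wt": WT, "rtt": RTT, WT.lower(): WT, RTT.lower(): RTT,
                 "mecp2null+": RTT, "mecp2": RTT}


def _group(name: str) -> str:
    key = _GENO_ALIASES.get(name.lower())
    if key is None:
        raise ValidationError(f"unknown genotype/preset {name!r}")
    return key


def ecg_preset(genotype: str, **overrides) -> ECGGenParams:
    """ECG generator parameters targeted at a genotype's group means."""
    g = ECG_GROUPS[_group(genotype)]
    base = dict(rr_mean=g["rr"][0], rr_sd=0.02 * g["rr"][0], pr=g["pr"][0],
                qrs=g["qrs"][0], qt=g["qt"][0], j_amp=g["j_amp"][0])
    base.update(overrides)
    return ECGGenParams(**base)


def ap_preset(genotype: str, **overrides) -> APGenParams:
    """AP-train generator parameters targeted at a genotype's group means."""
    key = _group(genotype)
    g = AP_GROUPS[key]
    bvr_mean = BVR_GROUPS[key][0]
    base = dict(rmp=g["rmp"][0], overshoot=g["overshoot"][0],
                v_max_target=g["v_max"][0], apd50_target=g["apd50"][0],
                apd90_target=g["apd90"][0],
                beat_to_beat_sd=bvr_mean * _BVR_TO_SD,
                threshold_stimulus=g["threshold_stimulus"][0])
    base.update(overrides)
    return APGenParams(**base)


def resp_preset(genotype: str, **overrides) -> RespGenParams:
    """Respiratory-flow generator parameters for a genotype."""
    key = _group(genotype)
    base = dict(breath_rate=RESP_RATE_GROUPS[key][0])
    base.update(overrides)
    return RespGenParams(**base)


# ------------------------------------------------------------------ cohort

@dataclass
class CohortSpec:
    """Cohort structure and scale.

    Group sizes default to the published design (ECG 12 WT / 15 Mecp2Null+,
    AP 24 / 18 cells, plethysmography 24 / 24).  Signal durations are scale
    knobs: analyses only need slightly more beats than the 5-complex ECG
    run and the 10-15 AP BVR train.
    """

    n_ecg: dict = field(default_factory=lambda: {WT: 12, RTT: 15})
    n_ap_cells: dict = field(default_factory=lambda: {WT: 24, RTT: 18})
    n_resp: dict = field(default_factory=lambda: {WT: 24, RTT: 24})
    ecg_n_beats: int = 12
    ecg_sampling_rate: float = 2000.0
    ap_n_aps: int = 12
    resp_adaptation_s: float = 300.0
    resp_window_s: float = 1200.0
    resp_sampling_rate: float = 100.0
    apnoea_rate_per_hour: float = 12.0
    apnoea_factor_range: dict = field(default_factory=lambda: {
        WT: (4.6, 5.6), RTT: (6.0, 9.0)})
    null: bool = False      # identical distributions (WT) for both labels
    seed: int | None = None

    def validate(self) -> None:
        for d in (self.n_ecg, self.n_ap_cells, self.n_resp):
            for g, n in d.items():
                if n < 2:
                    raise ValidationError(f"need >= 2 per group, got {n} for {g}")


@dataclass
class CohortData:
    ecg_animals: list
    ap_cells: list
    resp_animals: list
    parameter_truth: pd.DataFrame
    spec: CohortSpec


def _sd(mean_sem: tuple[float, float], n: int) -> float:
    return mean_sem[1] * np.sqrt(n)


def _truncated_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, max_tries=1000):
    for _ in range(max_tries):
        x = mean + sd * rng.standard_normal()
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-9, hi - 1e-9))


def _draw_ecg_params(rng, group: dict, n_beats: int, fs: float) -> ECGGenParams:
    n = group["n"]
    for _ in range(1000):
        rr = group["rr"][0] + _sd(group["rr"], n) * rng.standard_normal()
        pr = group["pr"][0] + _sd(group["pr"], n) * rng.standard_normal()
        qrs = group["qrs"][0] + _sd(group["qrs"], n) * rng.standard_normal()
        qt = group["qt"][0] + _sd(group["qt"], n) * rng.standard_normal()
        j = group["j_amp"][0] + _sd(group["j_amp"], n) * rng.standard_normal()
        # short-RR animals get more beats so every record spans >= 2 s
        beats = max(n_beats, int(np.ceil(2200.0 / max(rr, 40.0))) + 2)
        params = ECGGenParams(rr_mean=rr, rr_sd=0.02 * abs(rr), pr=pr, qrs=qrs,
                              qt=qt, j_amp=max(j, 0.06),
                              n_beats=beats, sampling_rate=fs,
                              seed=int(rng.integers(2 ** 31)))
        try:
            params.validate()
            return params
        except ValidationError:
            continue
    raise ValidationError("could not draw a valid ECG parameter set")


def _draw_ap_params(rng, group: dict, bvr: tuple, n_aps: int) -> APGenParams:
    n = group["n_cells"]
    for _ in range(1000):
        rmp = group["rmp"][0] + _sd(group["rmp"], n) * rng.standard_normal()
        overshoot = group["overshoot"][0] + _sd(group["overshoot"], n) \
            * rng.standard_normal()
        vmax = group["v_max"][0] + _sd(group["v_max"], n) * rng.standard_normal()
        apd50 = group["apd50"][0] + _sd(group["apd50"], n) * rng.standard_normal()
        apd90 = group["apd90"][0] + _sd(group["apd90"], n) * rng.standard_normal()
        thr = group["threshold_stimulus"][0] + \
            _sd(group["threshold_stimulus"], n) * rng.standard_normal()
        bvr_target = bvr[0] + bvr[1] * np.sqrt(bvr[2]) * rng.standard_normal()
        if overshoot - rmp < 60 or vmax < 40 or apd50 < 0.6:
            continue
        if apd90 < 7.0 * apd50 or apd90 > 450:
            continue
        params = APGenParams(rmp=rmp, overshoot=overshoot, v_max_target=vmax,
                             apd50_target=apd50, apd90_target=apd90,
                             beat_to_beat_sd=max(bvr_target, 0.3) * _BVR_TO_SD,
                             n_aps=n_aps, threshold_stimulus=max(thr, 50.0),
                             seed=int(rng.integers(2 ** 31)))
        try:
            params.validate()
            return params
        except ValidationError:
            continue
    raise ValidationError("could not draw a valid AP parameter set")


def _draw_resp_params(rng, genotype: str, spec: CohortSpec) -> RespGenParams:
    mean, sem, n = RESP_RATE_GROUPS[genotype]
    rate = _truncated_normal(rng, mean, sem * np.sqrt(n), 60.0, 180.0)
    duration = spec.resp_adaptation_s + spec.resp_window_s + 30.0
    lam = spec.apnoea_rate_per_hour * spec.resp_window_s / 3600.0
    k = min(int(rng.poisson(lam)), 10)
    lo, hi = spec.apnoea_factor_range[genotype]
    t0 = spec.resp_adaptation_s + 90.0
    t1 = spec.resp_adaptation_s + spec.resp_window_s - 30.0
    schedule = []
    if k > 0:
        slots = np.linspace(t0, t1, k + 1)
        gap = (t1 - t0) / (k + 1)
        for i in range(k):
            t = slots[i] + rng.uniform(0.2, 0.8) * gap
            schedule.append((float(t), float(rng.uniform(lo, hi))))
    return RespGenParams(breath_rate=rate, apnoea_schedule=schedule,
                         duration=duration,
                         sampling_rate=spec.resp_sampling_rate,
                         seed=int(rng.integers(2 ** 31)))


def generate_cohort(spec: CohortSpec | None = None) -> CohortData:
    """Generate per-animal signal bundles for both genotypes.

    Everything derives from ``spec.seed`` through independent child
    streams, so cohorts are reproducible bit-for-bit.  ``spec.null`` makes
    both labels draw from the WT distributions (a null cohort for
    calibration checks).
    """
    spec = spec or CohortSpec()
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ecg_ss, ap_ss, resp_ss = root.spawn(3)

    source_of = (lambda g: WT) if spec.null else (lambda g: g)

    ecg_animals, truth_rows = [], []
    streams = ecg_ss.spawn(sum(spec.n_ecg.values()))
    i = 0
    for genotype, n in spec.n_ecg.items():
        for a in range(n):
            rng = np.random.default_rng(streams[i]); i += 1
            params = _draw_ecg_params(rng, ECG_GROUPS[source_of(genotype)],
                                      spec.ecg_n_beats, spec.ecg_sampling_rate)
            signal, truth = generate_ecg(params)
            animal_id = f"{genotype}-{a:02d}"
            ecg_animals.append({"animal_id": animal_id, "genotype": genotype,
                                "signal": signal, "truth": truth,
                                "params": params})
            truth_rows.append({"record": animal_id, "arm": "ecg",
                               "genotype": genotype, "rr": params.rr_mean,
                               "pr": params.pr, "qrs": params.qrs,
                               "qt": params.qt})

    ap_cells = []
    streams = ap_ss.spawn(sum(spec.n_ap_cells.values()))
    i = 0
    for genotype, n in spec.n_ap_cells.items():
        for c in range(n):
            rng = np.random.default_rng(streams[i]); i += 1
            src = source_of(genotype)
            params = _draw_ap_params(rng, AP_GROUPS[src], BVR_GROUPS[src],
                                     spec.ap_n_aps)
            signal, truth, protocol, stim = generate_ap_train(params)
            cell_id = f"{genotype}-cell-{c:02d}"
            ap_cells.append({"cell_id": cell_id, "genotype": genotype,
                             "signal": signal, "truth": truth,
                             "protocol": protocol, "stim_times": stim,
                             "params": params})
            truth_rows.append({"record": cell_id, "arm": "ap",
                               "genotype": genotype,
                               "apd50": params.apd50_target,
                               "apd90": params.apd90_target,
                               "v_max": params.v_max_target})

    resp_animals = []
    streams = resp_ss.spawn(sum(spec.n_resp.values()))
    i = 0
    for genotype, n in spec.n_resp.items():
        for a in range(n):
            rng = np.random.default_rng(streams[i]); i += 1
            params = _draw_resp_params(rng, source_of(genotype), spec)
            signal, truth = generate_resp_flow(params)
            animal_id = f"{genotype}-{a:02d}"   # matches the ECG arm ids
            resp_animals.append({"animal_id": animal_id, "genotype": genotype,
                                 "signal": signal, "truth": truth,
                                 "params": params})
            truth_rows.append({"record": animal_id, "arm": "resp",
                               "genotype": genotype,
                               "breath_rate": params.breath_rate,
                               "n_scheduled": len(params.apnoea_schedule)})

    return CohortData(ecg_animals=ecg_animals, ap_cells=ap_cells,
                      resp_animals=resp_animals,
                      parameter_truth=pd.DataFrame(truth_rows), spec=spec)
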