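"""Genotype-level orchestration: group tables, comparisons and the
QTc-apnoea correlation.

``run_ecg_arm`` and ``run_ap_arm`` reduce per-animal / per-cell analyses to
group summaries (mean +/- SEM) and two-group tests per parameter.  Interval
parameters are compared with unpaired t-tests (equal/unequal variances
chosen by an F-test); beat-to-beat variability of repolarization (BVR) is
compared with the Mann-Whitney test.  Cells are treated as independent
observations within genotype, matching the published n-accounting.
``correlate_qtc_apnoea`` relates each animal's mean QTc (square-root
Mitchell correction, the convention used for this comparison) to its mean
apnoea length.

Every group statistic is recomputable from the emitted per-animal rows, and
a fixed seed plus fixed configuration reproduces identical result files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ap import (APConfig, compute_bvr, extract_ap_features, features_frame,
                 segment_aps)
from .ecg import ECGConfig, summarize_animal_ecg
from .errors import AnalysisError
from .io import write_results
from .respiration import RespConfig, analyze_respiration
from .stats import (CorrelationResult, GroupSummary, TestResult, mann_whitney,
                    mean_sem, pearson_corr, ttest_unpaired)
from .synth.cohort import CohortData, CohortSpec, generate_cohort

log = logging.getLogger("cardiophys.cohort")

__all__ = ["ArmResult", "run_ecg_arm", "run_ap_arm", "run_resp_arm",
           "correlate_qtc_apnoea", "run_cohort"]

ECG_PARAMETERS = ["rr_ms", "hr_bpm", "pr_ms", "qrs_ms", "qt_ms",
                  "qtc_mitchell_ms", "qtc_mccauley_ms"]
AP_PARAMETERS = ["resting_potential_mv", "overshoot_mv", "amplitude_mv",
                 "v_max_v_per_s", "apd10_ms", "apd25_ms", "apd50_ms",
                 "apd75_ms", "apd90_ms", "triangulation_ms",
                 "threshold_stimulus_pa"]


@dataclass
class ArmResult:
    """Rows, per-genotype summaries, and per-parameter test results."""

    rows: pd.DataFrame
    summaries: dict = field(default_factory=dict)   # param -> {geno: GroupSummary}
    tests: dict = field(default_factory=dict)       # param -> TestResult | None
    extra: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Printable group table: one row per parameter."""
        recs = []
        for param, by_geno in self.summaries.items():
            rec = {"parameter": param}
            for geno, s in by_geno.items():
                rec[f"{geno}_mean"] = s.mean
                rec[f"{geno}_sem"] = s.sem
                rec[f"{geno}_n"] = s.n
            t = self.tests.get(param)
            rec["p_value"] = t.p_value if t else float("nan")
            rec["test"] = t.test_name if t else ""
            recs.append(rec)
        return pd.DataFrame(recs)


def _summarize_and_test(rows: pd.DataFrame, parameters: list[str],
                        test_for: dict | None = None) -> tuple[dict, dict]:
    genotypes = list(dict.fromkeys(rows["genotype"]))
    summaries: dict = {}
    tests: dict = {}
    for param in parameters:
        if param not in rows.columns:
            continue
        by_geno = {}
        for geno in genotypes:
            vals = rows.loc[rows["genotype"] == geno, param].dropna()
            if len(vals):
                by_geno[geno] = mean_sem(vals, label=geno)
        summaries[param] = by_geno
        if len(genotypes) >= 2:
            a = rows.loc[rows["genotype"] == genotypes[0], param].dropna()
            b = rows.loc[rows["genotype"] == genotypes[1], param].dropna()
            if len(a) >= 3 and len(b) >= 3:
                test_fn = (test_for or {}).get(param, ttest_unpaired)
                tests[param] = test_fn(a, b)
            else:
                tests[param] = None
        else:
            tests[param] = None
    return summaries, tests


def run_ecg_arm(animals: list[dict], config: ECGConfig | None = None
                ) -> ArmResult:
    """Per-animal ECG summaries -> group table with unpaired tests.

    ``animals`` is a list of dicts with ``animal_id``, ``genotype`` and
    ``signal``.  Animals whose record cannot be analyzed are dropped with a
    log entry.
    """
    config = config or ECGConfig()
    rows = []
    for animal in animals:
        try:
            s = summarize_animal_ecg(animal["signal"], config)
        except AnalysisError as err:
            log.warning("ECG analysis failed for %s: %s", animal["animal_id"], err)
            continue
        rows.append({"animal_id": animal["animal_id"],
                     "genotype": animal["genotype"],
                     "rr_ms": s.rr_ms, "hr_bpm": s.hr_bpm, "pr_ms": s.pr_ms,
                     "qrs_ms": s.qrs_ms, "qt_ms": s.qt_ms,
                     "qtc_mitchell_ms": s.qtc_mitchell_ms,
                     "qtc_mccauley_ms": s.qtc_mccauley_ms,
                     "j_wave_mv": s.j_wave_mv})
    if not rows:
        raise AnalysisError("no animal yielded an ECG summary")
    frame = pd.DataFrame(rows)
    summaries, tests = _summarize_and_test(frame, ECG_PARAMETERS + ["j_wave_mv"])
    return ArmResult(rows=frame, summaries=summaries, tests=tests)


def run_ap_arm(cells: list[dict], config: APConfig | None = None) -> ArmResult:
    """Per-cell AP features and BVR -> group table.

    ``cells`` carry ``cell_id``, ``genotype``, ``signal``, ``protocol`` and
    optionally ``stim_times``.  Per-cell values are means over captured APs;
    BVR uses the first 10-15 APD90 values and is compared by Mann-Whitney.
    """
    config = config or APConfig()
    rows, poincare = [], []
    for cell in cells:
        try:
            windows = segment_aps(cell["signal"], cell["protocol"],
                                  cell.get("stim_times"), config)
            feats = [extract_ap_features(w, config) for w in windows if w.captured]
            if not feats:
                raise AnalysisError("no captured APs")
        except AnalysisError as err:
            log.warning("AP analysis failed for %s: %s", cell["cell_id"], err)
            continue
        table = features_frame(feats)
        row = {"cell_id": cell["cell_id"], "genotype": cell["genotype"],
               "n_aps": len(feats),
               "resting_potential_mv": table["resting_potential_mv"].mean(),
               "overshoot_mv": table["overshoot_mv"].mean(),
               "amplitude_mv": table["amplitude_mv"].mean(),
               "v_max_v_per_s": table["v_max_v_per_s"].mean(),
               "triangulation_ms": table["triangulation_ms"].mean(),
               "threshold_stimulus_pa": cell["protocol"].threshold_stimulus}
        for frac in (10, 25, 50, 75, 90):
            row[f"apd{frac}_ms"] = table[f"apd{frac}_ms"].mean()
        apd90 = table["apd90_ms"].to_numpy()
        n_missing = int(np.isnan(apd90).sum())
        try:
            bvr = compute_bvr(apd90, max_aps=config.bvr_max_aps)
            row["bvr_ms"] = bvr.bvr
            for x, y in bvr.poincare_pairs:
                poincare.append({"cell_id": cell["cell_id"],
                                 "genotype": cell["genotype"],
                                 "apd90_n": x, "apd90_n1": y})
        except AnalysisError:
            row["bvr_ms"] = float("nan")
        row["n_apd90_missing"] = n_missing
        rows.append(row)
    if not rows:
        raise AnalysisError("no cell yielded AP features")
    frame = pd.DataFrame(rows)
    summaries, tests = _summarize_and_test(
        frame, AP_PARAMETERS + ["bvr_ms"],
        test_for={"bvr_ms": mann_whitney})
    return ArmResult(rows=frame, summaries=summaries, tests=tests,
                     extra={"poincare": pd.DataFrame(poincare)})


def run_resp_arm(animals: list[dict], config: RespConfig | None = None
                 ) -> ArmResult:
    """Per-animal apnoea count and mean length -> group table."""
    config = config or RespConfig()
    rows = []
    for animal in animals:
        try:
            _, _, events, summary = analyze_respiration(animal["signal"], config)
        except AnalysisError as err:
            log.warning("respiration analysis failed for %s: %s",
                        animal["animal_id"], err)
            continue
        rows.append({"animal_id": animal["animal_id"],
                     "genotype": animal["genotype"],
                     "apnoea_count": summary.apnoea_count,
                     "mean_apnoea_length_s": summary.mean_apnoea_length})
    if not rows:
        raise AnalysisError("no animal yielded a respiration summary")
    frame = pd.DataFrame(rows)
    summaries, tests = _summarize_and_test(
        frame, ["apnoea_count", "mean_apnoea_length_s"])
    return ArmResult(rows=frame, summaries=summaries, tests=tests)


def correlate_qtc_apnoea(ecg_rows: pd.DataFrame, apnoea_rows: pd.DataFrame
                         ) -> tuple[CorrelationResult, pd.DataFrame]:
    """Pearson correlation of per-animal mean QTc (square-root correction)
    against mean apnoea length, over animals present in both arms."""
    merged = ecg_rows.merge(apnoea_rows, on="animal_id")
    dropped = set(ecg_rows["animal_id"]) ^ set(apnoea_rows["animal_id"])
    if dropped:
        log.info("QTc-apnoea correlation: %d unmatched animals excluded",
                 len(dropped))
    pairs = merged[["animal_id", "qtc_mitchell_ms", "mean_apnoea_length_s"]] \
        .dropna()
    if len(pairs) < 3:
        raise AnalysisError(
            f"only {len(pairs)} animals have both QTc and apnoea data")
    corr = pearson_corr(pairs["qtc_mitchell_ms"], pairs["mean_apnoea_length_s"])
    return corr, pairs


def run_cohort(spec: CohortSpec | None = None, output_dir: str | Path | None = None,
               ecg_config: ECGConfig | None = None,
               ap_config: APConfig | None = None) -> dict:
    """Generate a synthetic cohort and run every arm end-to-end.

    Returns a dict with the three :class:`ArmResult` objects and the
    QTc-apnoea correlation; when ``output_dir`` is given, writes
    ``table1.csv`` / ``table2.csv`` (group tables), ``correlation.json``,
    and the tidy per-animal tables.
    """
    spec = spec or CohortSpec()
    data = generate_cohort(spec)
    resp_config = RespConfig(adaptation_s=spec.resp_adaptation_s,
                             window_s=spec.resp_window_s)

    ecg = run_ecg_arm(data.ecg_animals, ecg_config)
    ap = run_ap_arm(data.ap_cells, ap_config)
    resp = run_resp_arm(data.resp_animals, resp_config)
    try:
        corr, corr_pairs = correlate_qtc_apnoea(ecg.rows, resp.rows)
    except AnalysisError as err:
        log.warning("QTc-apnoea correlation unavailable: %s", err)
        corr, corr_pairs = None, pd.DataFrame()

    result = {"ecg": ecg, "ap": ap, "resp": resp, "correlation": corr,
              "correlation_pairs": corr_pairs, "spec": spec}

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        ecg.table().to_csv(out / "table1.csv", index=False, float_format="%.12g")
        ap.table().to_csv(out / "table2.csv", index=False, float_format="%.12g")
        resp.table().to_csv(out / "respiration.csv", index=False,
                            float_format="%.12g")
        write_results({"correlation": corr}, out / "correlation.json",
                      rows=corr_pairs, config=spec, seed=spec.seed)
        write_results({"n_ecg": len(ecg.rows)}, out / "ecg_per_animal.json",
                      rows=ecg.rows, config=spec, seed=spec.seed)
        write_results({"n_cells": len(ap.rows)}, out / "ap_per_cell.json",
                      rows=ap.rows, config=spec, seed=spec.seed)
        write_results({"n_resp": len(resp.rows)}, out / "resp_per_animal.json",
                      rows=resp.rows, config=spec, seed=spec.seed)
    return result
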