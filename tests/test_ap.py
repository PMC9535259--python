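import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiophys.ap import (APConfig, APProtocol, APWindow, compute_bvr,
                           drug_effect, extract_ap_features, features_frame,
                           segment_aps)
from cardiophys.errors import AnalysisError, PairingError, ValidationError
from cardiophys.signal import SampledSignal
from cardiophys.synth import APGenParams, generate_ap_train
from cardiophys.synth.ap import solve_repolarization, true_apd


def idealized_window(fs=10000.0):
    """Instantaneous upstroke to +40 mV, linear ramp to -70 mV over 100 ms."""
    dt = 1.0 / fs
    n = int(0.4 * fs)
    x = np.full(n, -70.0)
    stim_i = int(0.1 * fs)
    ramp = int(0.1 * fs)
    x[stim_i:stim_i + ramp] = 40.0 - 110.0 * np.arange(ramp) / ramp
    return APWindow(samples=x, sampling_rate=fs, start_time=0.0,
                    stimulus_time=stim_i * dt, index=0, captured=True)


class TestSegmentation:
    def test_one_window_per_stimulus(self, wt_ap_train):
        _, signal, truth, protocol, stim = wt_ap_train
        windows = segment_aps(signal, protocol, stim)
        assert len(windows) == len(stim)
        assert all(w.captured for w in windows)

    def test_subthreshold_stimulus_flagged(self):
        params = APGenParams(seed=2, noise_sd=0.5, n_aps=12, skipped_beats=(4,))
        signal, truth, protocol, stim = generate_ap_train(params)
        windows = segment_aps(signal, protocol, stim)
        captured = [w.captured for w in windows]
        assert captured.count(False) == 1 and not captured[4]

    def test_auto_detected_onsets_close_to_stimuli(self):
        params = APGenParams(seed=6, noise_sd=0.5, n_aps=8)
        signal, truth, protocol, stim = generate_ap_train(params)
        windows = segment_aps(signal, protocol, None)
        detected = np.array([w.stimulus_time for w in windows])
        assert detected.size == stim.size
        assert np.abs(detected - stim).max() <= 1e-3

    def test_too_few_stimuli_rejected(self, wt_ap_train):
        _, signal, _, protocol, _ = wt_ap_train
        with pytest.raises(AnalysisError):
            segment_aps(signal, protocol, [0.25])


class TestFeatureExtraction:
    def test_linear_ramp_closed_form(self):
        f = extract_ap_features(idealized_window())
        assert f.resting_potential == pytest.approx(-70.0, abs=0.01)
        assert f.overshoot == pytest.approx(40.0, abs=0.2)
        for frac in (10, 25, 50, 75, 90):
            assert f.apd[frac] == pytest.approx(float(frac), abs=0.5)
        assert f.triangulation == pytest.approx(65.0, abs=1.0)

    def test_vmax_recovered(self):
        params = APGenParams(seed=8, noise_sd=0.5, n_aps=4)
        signal, truth, protocol, stim = generate_ap_train(params)
        for w in segment_aps(signal, protocol, stim):
            f = extract_ap_features(w)
            assert f.v_max == pytest.approx(150.1, abs=5.0)

    def test_rmp_amplitude_invariant(self, wt_ap_train):
        _, signal, truth, protocol, stim = wt_ap_train
        for w in segment_aps(signal, protocol, stim):
            f = extract_ap_features(w)
            assert f.amplitude == pytest.approx(f.overshoot - f.resting_potential)
            assert f.resting_potential == pytest.approx(-72.8, abs=0.5)

    def test_apd_monotone_in_fraction(self, rng):
        for _ in range(10):
            params = APGenParams(apd90_target=float(rng.uniform(80, 200)),
                                 noise_sd=0.5, n_aps=2,
                                 seed=int(rng.integers(2 ** 31)))
            signal, truth, protocol, stim = generate_ap_train(params)
            for w in segment_aps(signal, protocol, stim):
                f = extract_ap_features(w)
                apds = [f.apd[k] for k in (10, 25, 50, 75, 90)]
                assert np.all(np.diff(apds) >= 0)
                assert f.triangulation >= 0

    def test_noncaptured_window_rejected(self):
        w = idealized_window()
        w.captured = False
        with pytest.raises(AnalysisError):
            extract_ap_features(w)


class TestRepolSolver:
    @given(apd50=st.floats(1.0, 12.0), ratio=st.floats(8.0, 40.0))
    @settings(max_examples=30, deadline=None)
    def test_solver_hits_targets(self, apd50, ratio):
        apd90 = apd50 * ratio
        w, t1, t2 = solve_repolarization(apd50, apd90)
        assert true_apd(50, w, t1, t2) == pytest.approx(apd50, rel=1e-6)
        assert true_apd(90, w, t1, t2) == pytest.approx(apd90, rel=1e-6)

    def test_degenerate_targets_rejected(self):
        with pytest.raises(ValidationError):
            solve_repolarization(10.0, 10.0)


class TestBVR:
    def test_constant_series_zero(self):
        assert compute_bvr([150.0] * 10).bvr == 0.0

    def test_alternating_hand_example(self):
        res = compute_bvr([100.0, 102.0] * 5)
        assert res.bvr == pytest.approx(math.sqrt(2.0), abs=1e-12)
        assert len(res.poincare_pairs) == 9

    def test_missing_values_excluded_pairwise(self):
        series = [100.0, np.nan, 102.0, 100.0]
        res = compute_bvr(series)
        assert res.bvr == pytest.approx(2.0 / math.sqrt(2.0))

    def test_too_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            compute_bvr([100.0])

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 5.0),
           seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_affine_equivariance(self, shift, scale, seed):
        x = np.random.default_rng(seed).normal(120, 4, 12)
        base = compute_bvr(x).bvr
        assert compute_bvr(scale * x + shift).bvr == pytest.approx(
            abs(scale) * base, rel=1e-9)

    def test_closure_with_generator(self, wt_ap_train):
        # extractor + BVR reproduces the generator's own APD90 variability
        _, signal, truth, protocol, stim = wt_ap_train
        feats = [extract_ap_features(w)
                 for w in segment_aps(signal, protocol, stim) if w.captured]
        measured = compute_bvr([f.apd90 for f in feats]).bvr
        true = compute_bvr(truth.apd90.to_numpy()).bvr
        assert measured == pytest.approx(true, rel=0.15)


class TestDrugEffect:
    def make_table(self, apd90, tri):
        import pandas as pd
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(apd90))],
                             "apd90_ms": apd90, "triangulation_ms": tri})

    def test_identity_gives_zero_change(self):
        t = self.make_table([150.0, 140.0, 160.0], [110.0, 100.0, 120.0])
        res = drug_effect(t, t)
        assert np.allclose(res["per_cell"]["apd90_pct_change"], 0.0)
        assert res["tests"]["apd90"].p_value == 1.0

    def test_percent_change_arithmetic(self):
        pre = self.make_table([150.0, 150.0, 150.0], [110.0] * 3)
        post = self.make_table([120.0, 120.0, 120.0], [90.0] * 3)
        res = drug_effect(pre, post)
        assert np.allclose(res["per_cell"]["apd90_pct_change"], -20.0)

    def test_unmatched_cells_rejected(self):
        pre = self.make_table([150.0, 140.0], [110.0, 100.0])
        post = self.make_table([120.0, 130.0], [90.0, 95.0])
        post["cell_id"] = ["c0", "zz"]
        with pytest.raises(PairingError):
            drug_effect(pre, post)

    def test_detects_triangulation_decrease(self, rng):
        # pre/post means follow the reported acute drug effect in the
        # disease group (134.1 -> 110.2 ms across 8 cells)
        pre_t = rng.normal(134.1, 12.0, 8)
        shift = rng.normal(-23.9, 6.0, 8)
        pre = self.make_table(rng.normal(180, 15, 8), pre_t)
        post = self.make_table(pre["apd90_ms"] * 0.85, pre_t + shift)
        res = drug_effect(pre, post)
        t = res["tests"]["triangulation"]
        assert t.statistic < 0 and t.p_value < 0.05
        assert res["triangulation_change_ms"].mean < 0
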