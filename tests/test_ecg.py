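import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiophys.ecg import (ECGConfig, FiducialSet, delineate_complex,
                            detect_r_peaks, measure_intervals, qtc_mccauley,
                            qtc_mitchell, select_clean_complexes,
                            summarize_animal_ecg)
from cardiophys.errors import AnalysisError, ValidationError
from cardiophys.signal import SampledSignal
from cardiophys.synth import ECGGenParams, generate_ecg


class TestRPeakDetection:
    def test_flat_trace_yields_empty_with_warning(self):
        flat = SampledSignal(np.zeros(6000), 2000.0)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            r = detect_r_peaks(flat)
        assert r.size == 0 and len(caught) == 1

    def test_beat_count_and_spacing(self):
        params = ECGGenParams(rr_mean=150.0, rr_sd=0.0, qt=50.0, n_beats=20,
                              noise_sd=0.01, seed=5)
        signal, truth = generate_ecg(params)
        r = detect_r_peaks(signal)
        assert r.size == 20
        np.testing.assert_allclose(np.diff(r) * 1e3, 150.0, atol=1.0)

    def test_polarity_inversion_symmetry(self, wt_ecg):
        _, signal, _ = wt_ecg
        r1 = detect_r_peaks(signal)
        flipped = SampledSignal(-signal.samples, signal.sampling_rate)
        r2 = detect_r_peaks(flipped)
        assert np.abs(r1 - r2).max() <= 1.0 / signal.sampling_rate

    def test_strictly_increasing_with_refractory(self, wt_ecg):
        _, signal, _ = wt_ecg
        r = detect_r_peaks(signal)
        assert np.all(np.diff(r) >= 0.040)

    def test_short_record_rejected(self):
        with pytest.raises(AnalysisError):
            detect_r_peaks(SampledSignal(np.zeros(1000), 1000.0))

    def test_low_rate_rejected(self):
        with pytest.raises(ValidationError):
            detect_r_peaks(SampledSignal(np.zeros(1000), 500.0))


class TestCleanComplexSelection:
    def test_noise_free_returns_first_run(self, wt_ecg):
        _, signal, _ = wt_ecg
        r = detect_r_peaks(signal)
        np.testing.assert_array_equal(select_clean_complexes(signal, r, 5),
                                      [0, 1, 2, 3, 4])

    def test_interference_burst_excluded(self):
        base = ECGGenParams(seed=3, noise_sd=0.005)
        clean_sig, truth = generate_ecg(base)
        start = truth.r_time[2] - 0.03
        dur = truth.r_time[3] - truth.r_time[2] + 0.06
        params = ECGGenParams(seed=3, noise_sd=0.005,
                              interference_bursts=[(start, dur, 0.15)])
        signal, _ = generate_ecg(params)
        r = detect_r_peaks(signal)
        idx = select_clean_complexes(signal, r, 5)
        assert idx[0] >= 4          # beats 2-3 (and their windows) skipped
        assert 2 not in idx and 3 not in idx

    def test_fully_contaminated_record_raises(self):
        params = ECGGenParams(seed=3, noise_sd=0.005, n_beats=14,
                              interference_bursts=[(0.0, 10.0, 0.15)])
        signal, _ = generate_ecg(params)
        r = detect_r_peaks(signal)
        with pytest.raises(AnalysisError, match="longest clean run"):
            select_clean_complexes(signal, r, 5)


class TestDelineation:
    def test_fiducials_recover_generator_truth(self, wt_ecg):
        _, signal, truth = wt_ecg
        r = detect_r_peaks(signal)
        fid = delineate_complex(signal, r[3], truth.rr_ms[3])
        row = truth.iloc[3]
        qt = (fid.qt_end_time - fid.qrs_onset_time) * 1e3
        qrs = (fid.qrs_end_time - fid.qrs_onset_time) * 1e3
        pr = (fid.qrs_onset_time - fid.p_onset_time) * 1e3
        assert qt == pytest.approx(row.qt_ms, abs=2.0)
        assert qrs == pytest.approx(row.qrs_ms, abs=1.0)
        assert pr == pytest.approx(row.pr_ms, abs=2.0)

    def test_j_wave_absent_when_not_generated(self):
        params = ECGGenParams(seed=9, noise_sd=0.005, j_wave_present=False)
        signal, truth = generate_ecg(params)
        r = detect_r_peaks(signal)
        fid = delineate_complex(signal, r[2], truth.rr_ms[2])
        assert np.isnan(fid.j_peak_amplitude)

    def test_j_wave_amplitude_recovered(self):
        # amplitude set to the disease-group mean J-wave height
        params = ECGGenParams(seed=9, noise_sd=0.005, j_amp=0.25)
        signal, truth = generate_ecg(params)
        r = detect_r_peaks(signal)
        fid = delineate_complex(signal, r[2], truth.rr_ms[2])
        assert fid.j_peak_amplitude == pytest.approx(0.25, abs=0.03)

    def test_fiducial_ordering_enforced(self):
        with pytest.raises(ValidationError):
            FiducialSet(r_peak_time=1.0, qrs_onset_time=1.1,
                        qrs_end_time=1.2, t_peak_time=1.3, qt_end_time=1.4)


class TestIntervals:
    def make_fid(self, t0, qt_ms=53.3, qrs_ms=12.0):
        return FiducialSet(r_peak_time=t0 + 6e-3, qrs_onset_time=t0,
                           qrs_end_time=t0 + qrs_ms * 1e-3,
                           t_peak_time=t0 + 0.040,
                           qt_end_time=t0 + qt_ms * 1e-3)

    def test_definitions(self):
        fids = [self.make_fid(0.0), self.make_fid(0.150)]
        table = measure_intervals(fids)
        assert table.qt_ms[0] == pytest.approx(53.3)
        assert table.rr_ms[0] == pytest.approx(150.0)
        assert table.hr_bpm[0] == pytest.approx(400.0)

    def test_single_complex_needs_next_r(self):
        with pytest.raises(AnalysisError):
            measure_intervals([self.make_fid(0.0)])
        table = measure_intervals([self.make_fid(0.0)], next_r_time=0.106)
        assert table.rr_ms[0] == pytest.approx(100.0)

    def test_qt_longer_than_rr_rejected(self):
        fids = [self.make_fid(0.0, qt_ms=60.0), self.make_fid(0.050, qt_ms=60.0)]
        with pytest.raises(AnalysisError):
            measure_intervals(fids)


class TestQTc:
    def test_mitchell_reference_and_values(self):
        assert qtc_mitchell(53.3, 100.0) == pytest.approx(53.3)
        assert qtc_mitchell(53.3, 154.4) == pytest.approx(42.9, abs=0.05)
        assert qtc_mitchell(56.3, 134.9) == pytest.approx(48.5, abs=0.05)

    def test_mccauley_reference_and_values(self):
        assert qtc_mccauley(47.0, 170.0) == pytest.approx(47.0)
        assert qtc_mccauley(53.3, 154.4) == pytest.approx(58.2, abs=0.05)
        assert qtc_mccauley(56.3, 134.9) == pytest.approx(67.4, abs=0.05)

    def test_nonpositive_inputs_rejected(self):
        for fn in (qtc_mitchell, qtc_mccauley):
            with pytest.raises(ValidationError):
                fn(-1.0, 150.0)
            with pytest.raises(ValidationError):
                fn(50.0, 0.0)

    @given(qt=st.floats(30, 80), rr=st.lists(st.floats(80, 220),
                                             min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_mccauley_commutes_with_averaging(self, qt, rr):
        rr = np.asarray(rr)
        per_beat = qtc_mccauley(np.full(rr.size, qt), rr)
        assert np.mean(per_beat) == pytest.approx(
            qtc_mccauley(qt, float(np.mean(rr))), abs=1e-9)

    @given(qt=st.floats(30, 80), rr1=st.floats(80, 219), dr=st.floats(0.5, 100))
    @settings(max_examples=50, deadline=None)
    def test_mitchell_decreasing_in_rr(self, qt, rr1, dr):
        assert qtc_mitchell(qt, rr1 + dr) < qtc_mitchell(qt, rr1)


class TestAnimalSummary:
    def test_recovery_of_generator_truth(self, wt_ecg):
        params, signal, truth = wt_ecg
        s = summarize_animal_ecg(signal)
        run = truth.iloc[s.first_beat_index:s.first_beat_index + s.n_complexes]
        assert s.qt_ms == pytest.approx(params.qt, abs=2.0)
        assert s.rr_ms == pytest.approx(run.rr_ms.mean(), abs=1.0)
        assert s.qrs_ms == pytest.approx(params.qrs, abs=1.0)
        assert s.pr_ms == pytest.approx(params.pr, abs=2.0)

    def test_deterministic_on_identical_records(self, wt_ecg):
        _, signal, _ = wt_ecg
        s1 = summarize_animal_ecg(signal)
        s2 = summarize_animal_ecg(signal)
        assert s1.qt_ms == s2.qt_ms and s1.qtc_mccauley_ms == s2.qtc_mccauley_ms

    def test_record_with_too_few_beats_rejected(self):
        params = ECGGenParams(seed=4, n_beats=5, rr_mean=500.0, rr_sd=0.0,
                              qt=60.0, pr=46.1)
        signal, _ = generate_ecg(params)
        with pytest.raises(AnalysisError):
            summarize_animal_ecg(signal)

    def test_sampling_rate_robustness(self):
        qts = []
        for fs in (10000.0, 2000.0):
            params = ECGGenParams(seed=11, noise_sd=0.0, sampling_rate=fs)
            signal, _ = generate_ecg(params)
            qts.append(summarize_animal_ecg(signal).qt_ms)
        assert abs(qts[0] - qts[1]) <= 1.0
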