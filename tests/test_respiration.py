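import numpy as np
import pandas as pd
import pytest

from cardiophys.errors import AnalysisError, ValidationError
from cardiophys.respiration import (RespConfig, detect_apnoeas,
                                    running_expiration_average,
                                    segment_breaths, summarize_apnoeas,
                                    analyze_respiration)
from cardiophys.signal import SampledSignal
from cardiophys.synth import RespGenParams, generate_resp_flow


def breaths_table(expiration_times, period=0.5):
    """Hand-built breath table with the given expiration times."""
    rows, t = [], 0.0
    for k, te in enumerate(expiration_times):
        ti = period - min(te, period / 2) if te < period else period / 2
        rows.append({"breath_index": k, "inspiration_start": t,
                     "expiration_start": t + ti, "expiration_end": t + ti + te,
                     "expiration_time": te})
        t += ti + te
    return pd.DataFrame(rows)


class TestSegmentation:
    def test_sinusoid_half_period_expiration(self):
        t = np.arange(0, 120, 0.01)
        flow = SampledSignal(np.sin(2 * np.pi * 2.0 * t), 100.0)
        breaths = segment_breaths(flow)
        assert np.allclose(breaths.expiration_time, 0.25, atol=0.005)

    def test_inserted_expiratory_pause_measured(self):
        params = RespGenParams(breath_rate=120, duration=200, seed=9,
                               apnoea_schedule=[(80.0, 5.45)])
        signal, truth = generate_resp_flow(params)
        breaths = segment_breaths(signal)
        i = truth.index[truth.is_apnoea][0]
        assert breaths.expiration_time[i] == pytest.approx(
            truth.expiration_time[i], abs=0.02)

    def test_sign_flip_with_polarity_flag(self):
        params = RespGenParams(breath_rate=110, duration=100, seed=2)
        signal, _ = generate_resp_flow(params)
        b1 = segment_breaths(signal, RespConfig())
        flipped = SampledSignal(-signal.samples, signal.sampling_rate)
        b2 = segment_breaths(flipped, RespConfig(polarity="neg"))
        np.testing.assert_allclose(b1.expiration_time, b2.expiration_time,
                                   atol=1e-9)

    def test_short_record_rejected(self):
        with pytest.raises(AnalysisError):
            segment_breaths(SampledSignal(np.sin(np.arange(100)), 100.0))

    def test_breath_rate_recovered(self):
        params = RespGenParams(breath_rate=120, duration=120, seed=1)
        signal, truth = generate_resp_flow(params)
        breaths = segment_breaths(signal)
        rate = 60.0 * len(breaths) / signal.duration
        assert rate == pytest.approx(120.0, abs=2.0)


class TestRunningAverage:
    def test_constant_breathing(self):
        breaths = breaths_table([0.25] * 400)
        baseline = running_expiration_average(breaths)
        t = breaths["expiration_start"].to_numpy()
        assert np.all(np.isnan(baseline[t < 60.0]))
        assert np.allclose(baseline[t >= 60.0], 0.25)

    def test_step_change_transitions_within_one_window(self):
        te = [0.2] * 600 + [0.3] * 600
        breaths = breaths_table(te)
        baseline = running_expiration_average(breaths)
        t_step = breaths["expiration_start"][600]
        t = breaths["expiration_start"].to_numpy()
        assert np.allclose(baseline[(t > 120) & (t < t_step)], 0.2, atol=1e-9)
        after = baseline[t > t_step + 120.0]
        assert np.allclose(after, 0.3, atol=1e-9)

    def test_outlier_inflates_next_window_by_weighted_share(self):
        te = [0.25] * 130 + [1.25] + [0.25] * 260
        breaths = breaths_table(te)
        baseline = running_expiration_average(breaths)
        t_out = breaths["expiration_end"][130]
        tick = (np.floor(t_out / 60.0) + 1) * 60.0
        in_win = breaths.loc[(breaths.expiration_end > tick - 60)
                             & (breaths.expiration_end <= tick),
                             "expiration_time"]
        affected = baseline[(breaths.expiration_start >= tick)
                            & (breaths.expiration_start < tick + 60)]
        assert np.allclose(affected, in_win.mean(), atol=1e-12)


class TestApnoeaDetection:
    def test_constant_breathing_no_events(self):
        breaths = breaths_table([0.25] * 4000)
        cfg = RespConfig(adaptation_s=60.0, window_s=1000.0)
        baseline = running_expiration_average(breaths, cfg)
        assert detect_apnoeas(breaths, baseline, cfg) == []

    def test_exactly_four_times_is_not_an_event(self):
        te = [0.25] * 299 + [1.0] + [0.25] * 200   # exactly 4.0 x baseline
        breaths = breaths_table(te)
        cfg = RespConfig(adaptation_s=0.0, window_s=1e6)
        baseline = running_expiration_average(breaths, cfg)
        events = detect_apnoeas(breaths, baseline, cfg)
        assert events == []
        te[299] = 1.001   # strictly greater -> an event
        breaths = breaths_table(te)
        baseline = running_expiration_average(breaths, cfg)
        assert len(detect_apnoeas(breaths, baseline, cfg)) == 1

    def test_scheduled_events_recovered(self):
        sched = [(1300.0, 5.0), (2000.0, 4.5), (3500.0, 6.0)]
        params = RespGenParams(breath_rate=120, apnoea_schedule=sched,
                               duration=4900, seed=4)
        signal, truth = generate_resp_flow(params)
        _, _, events, summary = analyze_respiration(signal)
        assert summary.apnoea_count == 3
        true_len = truth.loc[truth.is_apnoea, "expiration_time"].to_numpy()
        got = np.array([e.length for e in events])
        np.testing.assert_allclose(got, true_len, rtol=0.05)

    def test_time_scale_invariance_of_count(self):
        te = [0.25] * 500
        te[300] = 1.25
        cfg = RespConfig(adaptation_s=0.0, window_s=1e6)
        counts = []
        for scale in (1.0, 3.0):
            breaths = breaths_table([scale * x for x in te],
                                    period=0.5 * scale)
            baseline = running_expiration_average(breaths, cfg)
            counts.append(len(detect_apnoeas(breaths, baseline, cfg)))
        assert counts[0] == counts[1] == 1

    def test_no_events_from_adaptation_period(self):
        sched = [(600.0, 6.0), (1500.0, 6.0)]
        params = RespGenParams(breath_rate=110, apnoea_schedule=sched,
                               duration=2000, seed=3)
        signal, _ = generate_resp_flow(params)
        cfg = RespConfig(adaptation_s=1200.0, window_s=3600.0)
        _, _, events, _ = analyze_respiration(signal, cfg)
        assert len(events) == 1 and events[0].time >= 1200.0


class TestSummary:
    def test_zero_events(self):
        s = summarize_apnoeas([])
        assert s.apnoea_count == 0 and np.isnan(s.mean_apnoea_length)

    def test_mean_length(self):
        from cardiophys.respiration import ApnoeaEvent
        events = [ApnoeaEvent(0, 10.0, 1.0, 0.2),
                  ApnoeaEvent(1, 20.0, 1.2, 0.2),
                  ApnoeaEvent(2, 30.0, 1.4, 0.2)]
        s = summarize_apnoeas(events)
        assert s.apnoea_count == 3
        assert s.mean_apnoea_length == pytest.approx(1.2)


class TestGeneratorValidation:
    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValidationError):
            RespGenParams(apnoea_schedule=[(100.0, 5.0), (100.5, 5.0)],
                          duration=600).validate()

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValidationError):
            RespGenParams(apnoea_schedule=[(100.0, 0.9)],
                          duration=600).validate()

    def test_empty_schedule_truth_has_no_apnoeas(self):
        params = RespGenParams(duration=90, seed=0)
        _, truth = generate_resp_flow(params)
        assert truth.is_apnoea.sum() == 0
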