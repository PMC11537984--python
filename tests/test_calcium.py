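"""Trace normalisation, the 3xSD transient detector, and half-peak timing."""

import numpy as np
import pytest

from pericap import calcium as ca
from pericap import synthetic as sy


def _trace(values, rate_hz=2.0, baseline_s=60.0, normalized=False):
    t = np.arange(len(values)) / rate_hz
    return ca.CalciumTrace(t, np.asarray(values, float), (0.0, baseline_s),
                           normalized=normalized)


class TestNormalize:
    def test_constant_trace_normalises_to_one(self):
        tr = ca.normalize_trace(_trace(np.full(600, 200.0)))
        np.testing.assert_allclose(tr.values, 1.0)

    def test_value_relative_to_baseline_mean(self):
        v = np.full(600, 100.0)
        v[300] = 150.0
        tr = ca.normalize_trace(_trace(v))
        assert tr.values[300] == pytest.approx(1.5)

    def test_idempotent(self):
        tr = ca.normalize_trace(_trace(np.full(600, 200.0)))
        again = ca.normalize_trace(tr)
        assert np.array_equal(tr.values, again.values)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ca.normalize_trace(_trace(np.full(600, -5.0)))


class TestDetectTransients:
    def test_constant_trace_yields_no_events(self):
        tr = ca.normalize_trace(_trace(np.full(600, 100.0)))
        assert ca.detect_transients(tr) == []

    def test_unnormalised_trace_rejected(self):
        with pytest.raises(ValueError, match="normalis"):
            ca.detect_transients(_trace(np.full(600, 100.0)))

    def test_five_large_events_detected_at_injected_times(self):
        rng = np.random.default_rng(4)
        n = 600
        v = 100.0 + rng.normal(0, 5.0, n)
        event_samples = [150, 220, 300, 420, 540]
        for k in event_samples:
            v[k:] += 50.0 * np.exp(-(np.arange(n - k) / 2.0) / 2.0)  # 10 x SD
        tr = ca.normalize_trace(_trace(v))
        events = ca.detect_transients(tr)
        onsets = np.array([e.onset_s for e in events])
        assert len(events) == 5
        for k in event_samples:
            assert np.min(np.abs(onsets - k / 2.0)) <= 0.5  # within one sample

    def test_sub_threshold_event_never_detected(self):
        # peak placed exactly at 2.9 x the detector's own SD estimate
        for seed in range(30):
            rng = np.random.default_rng(seed)
            v = 100.0 + rng.normal(0, 5.0, 600)
            tr0 = ca.normalize_trace(_trace(v.copy()))
            base = tr0.baseline_slice()
            mu, sd = float(np.median(base)), ca.baseline_noise_sd(tr0)
            w = tr0.values.copy()
            w[200:] = mu                      # quiet after the baseline window
            w[400] = mu + 2.9 * sd
            tr = _trace(w, normalized=True)
            hits = [e for e in ca.detect_transients(tr)
                    if abs(e.onset_s - 200.0) < 1.0]
            assert hits == []

    def test_detection_invariant_to_affine_rescaling_before_normalisation(self):
        st = sy.gen_trace(sy.TraceSpec(transient_rate_per_30s=2.0), seed=6)
        raw = st.trace
        events_a = ca.detect_transients(ca.normalize_trace(raw))
        rescaled = ca.CalciumTrace(
            raw.times_s, 2.5 * raw.values + 40.0, raw.baseline_window_s
        )
        events_b = ca.detect_transients(ca.normalize_trace(rescaled))
        assert [e.onset_s for e in events_a] == [e.onset_s for e in events_b]

    def test_false_positive_rate_on_pure_noise(self):
        rates = []
        for seed in range(400):
            st = sy.gen_trace(sy.TraceSpec(transient_rate_per_30s=0.0), seed=seed)
            n = len(ca.detect_transients(ca.normalize_trace(st.trace)))
            rates.append(n * 30.0 / 300.0)
        assert np.mean(rates) < 0.2

    def test_rate_recovery_slope_near_unity_at_6sd_biological_rates(self):
        xs, ys = [], []
        for lam in (0.5, 1.0, 1.85, 2.6):
            spec = sy.TraceSpec(transient_rate_per_30s=lam, transient_amp_sd=6.0)
            rec, inj = [], []
            for seed in range(100):
                st = sy.gen_trace(spec, seed=seed)
                ev = ca.detect_transients(ca.normalize_trace(st.trace))
                rec.append(len(ev) * 30 / spec.duration_s)
                inj.append(len(st.event_times_s) * 30 / spec.duration_s)
            xs.append(np.mean(inj))
            ys.append(np.mean(rec))
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


class TestSummarize:
    def test_rate_per_30s(self):
        events = [ca.TransientEvent(i * 10.0, i * 10.0, 1.0, 1.0) for i in range(6)]
        s = ca.summarize_transients(events, duration_s=180.0)
        assert s.rate_per_30s == pytest.approx(1.0)
        assert s.n_events == 6

    def test_empty_events_rate_zero_amplitude_flagged(self):
        s = ca.summarize_transients([], duration_s=300.0)
        assert s.rate_per_30s == 0.0
        assert np.isnan(s.mean_amplitude)

    def test_poisson_rate_recovered_within_sampling_error(self):
        rates = []
        for seed in range(200):
            st = sy.gen_trace(sy.TraceSpec(transient_rate_per_30s=2.0), seed=seed)
            ev = ca.detect_transients(ca.normalize_trace(st.trace))
            rates.append(ca.summarize_transients(ev, 300.0).rate_per_30s)
        se = np.sqrt(2.0 / 10) / np.sqrt(200)  # Poisson SE of the mean rate
        # small positive bias from the noise false-positive floor is allowed
        assert abs(np.mean(rates) - 2.0) < 2 * se + 0.16


class TestTimeToHalfPeak:
    def test_linear_ramp_halfway(self):
        t = np.arange(0, 20.01, 0.1)
        v = np.clip((t - 5.0) / 10.0, 0, 1)
        res = ca.time_to_half_peak(t, v, onset=5.0)
        assert res.direction == "rise"
        # plateau mean (final 20%) sits slightly below 1; allow half-level shift
        assert res.t_half == pytest.approx(5.0, abs=0.3)

    def test_instantaneous_step_is_zero_within_sample(self):
        t = np.arange(0, 20.01, 0.1)
        v = np.where(t >= 5.0, 1.0, 0.0)
        res = ca.time_to_half_peak(t, v, onset=5.0)
        assert 0.0 <= res.t_half <= 0.2

    def test_logistic_midpoint_recovered(self):
        tc = sy.gen_timecourse(seed=8, midpoint_min=8.41)
        res = ca.time_to_half_peak(tc.times_min, tc.values, tc.onset_min)
        assert res.t_half == pytest.approx(8.41, abs=0.3)

    def test_t_half_monotone_in_generator_midpoint(self):
        recovered = []
        for mid in (4.0, 6.0, 8.0, 10.0):
            tc = sy.gen_timecourse(seed=3, midpoint_min=mid)
            recovered.append(
                ca.time_to_half_peak(tc.times_min, tc.values, tc.onset_min).t_half
            )
        assert all(a < b for a, b in zip(recovered, recovered[1:]))

    def test_falling_response_detected(self):
        t = np.arange(0, 20.01, 0.1)
        v = np.where(t >= 5.0, -1.0, 0.0)
        assert ca.time_to_half_peak(t, v, onset=5.0).direction == "fall"

    def test_missing_pre_onset_baseline_rejected(self):
        t = np.arange(0, 20.01, 0.1)
        v = np.linspace(0, 1, t.size)
        with pytest.raises(ValueError, match="baseline"):
            ca.time_to_half_peak(t, v, onset=-1.0)

    def test_identical_baseline_and_plateau_rejected(self):
        t = np.arange(0, 20.01, 0.1)
        with pytest.raises(ValueError, match="identical"):
            ca.time_to_half_peak(t, np.zeros_like(t), onset=5.0)
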