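"""Trace quantification: normalization, spike calling, decay, intervals."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calnet.metrics import (Trace, TraceError, analyze_trace, classify_oscillation,
                            detect_spikes, first_interval, half_decay, normalize,
                            occurrence_rate, read_trace_csv, synchronization_index,
                            analyze_population, metrics_frame, population_summary)


def make_trace(signal, dt=0.5, onset=30.0, normalized=False):
    t = np.arange(len(signal)) * dt
    return Trace(t, np.asarray(signal, dtype=float), onset=onset,
                 normalized=normalized)


def planted(peaks, dt=0.5, duration=300.0, onset=30.0, ratio=5.0, tau=10.0,
            baseline=1.0):
    """Baseline-1 signal with sharp transients at the given times."""
    t = np.arange(0, duration, dt)
    y = np.full_like(t, baseline)
    for tp in peaks:
        after = t >= tp
        y[after] += baseline * (ratio - 1) * np.exp(-(t[after] - tp) / tau)
    return Trace(t, y, onset=onset, normalized=(baseline == 1.0))


class TestNormalize:
    def test_constant_signal_becomes_one(self):
        tr = normalize(make_trace(np.full(600, 500.0)))
        assert np.allclose(tr.signal, 1.0)

    def test_peak_ratio_preserved(self):
        y = np.full(600, 200.0)
        y[100] = 800.0
        tr = normalize(make_trace(y))
        assert tr.signal.max() == pytest.approx(4.0)

    @given(st.floats(0.01, 1e6))
    @settings(max_examples=20, deadline=None)
    def test_gain_invariance(self, k):
        y = np.full(600, 100.0)
        y[90:110] += 300.0
        a = normalize(make_trace(y)).signal
        b = normalize(make_trace(y * k)).signal
        assert np.allclose(a, b, rtol=1e-12)

    def test_missing_baseline_window_raises(self):
        with pytest.raises(TraceError):
            normalize(make_trace(np.ones(600), onset=1.0))


class TestDetectSpikes:
    def test_flat_noisy_trace_no_spikes(self):
        rng = np.random.default_rng(0)
        tr = make_trace(1.0 + 0.01 * rng.standard_normal(600), normalized=True)
        times, _ = detect_spikes(tr)
        assert times.size == 0

    def test_three_planted_transients_found(self):
        tr = planted([50, 120, 200])
        times, amps = detect_spikes(tr)
        assert times.size == 3
        assert np.allclose(times, [50, 120, 200], atol=0.5)
        assert np.all(amps > 3)

    def test_threshold_is_strict(self):
        """A transient peaking at ratio exactly 3.0 is not counted."""
        t = np.arange(0, 300, 0.5)
        def transient(peak):
            y = np.ones_like(t)
            hold = (t >= 100) & (t < 103)      # flat-top transient
            y[hold] = peak
            fall = t >= 103
            y[fall] += (peak - 1) * np.exp(-(t[fall] - 103) / 10.0)
            return Trace(t, y, onset=30.0, normalized=True)
        assert detect_spikes(transient(3.0))[0].size == 0
        assert detect_spikes(transient(3.0 + 1e-9))[0].size == 1

    def test_rearm_rule_merges_shoulder_peaks(self):
        """Two maxima without a return below the re-arm level are one spike."""
        t = np.arange(0, 300, 0.5)
        y = np.ones_like(t)
        bump = (t >= 50) & (t < 80)
        y[bump] = 5.0
        y[(t >= 60) & (t < 62)] = 4.5   # dip that stays above re-arm (2.0)
        tr = Trace(t, y, onset=30.0, normalized=True)
        times, _ = detect_spikes(tr)
        assert times.size == 1

    def test_threshold_monotonicity(self):
        tr = planted([60, 130, 210], ratio=6.0)
        counts = [detect_spikes(tr, thr)[0].size for thr in (2, 3, 4, 5, 7)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_pre_onset_samples_ignored(self):
        tr = planted([50])
        # insert a pre-onset artifact
        y = tr.signal.copy()
        y[10] = 9.0
        tr2 = Trace(tr.time, y, onset=30.0, normalized=True)
        times, _ = detect_spikes(tr2)
        assert times.size == 1 and times[0] == pytest.approx(50, abs=0.5)


class TestClassifyAndInterval:
    @pytest.mark.parametrize("n,expected", [(0, False), (1, False), (2, True),
                                            (5, True)])
    def test_oscillation_needs_two_spikes(self, n, expected):
        assert classify_oscillation(np.arange(n, dtype=float)) is expected

    def test_first_interval(self):
        assert first_interval(np.array([10.0, 40.0, 90.0])) == pytest.approx(30.0)
        assert first_interval(np.array([10.0])) is None

    def test_periodic_planting_recovered(self):
        tr = planted([50, 75, 100, 125], tau=4.0)
        times, _ = detect_spikes(tr)
        assert first_interval(times) == pytest.approx(25.0, abs=0.5)


class TestHalfDecay:
    def test_reciprocal_identity(self):
        tr = planted([60.0], tau=20.0)
        times, amps = detect_spikes(tr)
        hd, dr = half_decay(tr, times, amps)
        assert hd is not None
        assert dr * hd == pytest.approx(1.0)
        # exponential fall: analytic half-decay = tau*ln(2)
        assert hd == pytest.approx(20.0 * np.log(2), rel=0.05)

    def test_reported_decay_scale_consistency(self):
        """A 114.9 s half decay corresponds to a 0.0087 s⁻¹ rate."""
        tr = planted([40.0], tau=114.9 / np.log(2), duration=600.0)
        times, amps = detect_spikes(tr)
        hd, dr = half_decay(tr, times, amps)
        assert dr == pytest.approx(0.0087, rel=0.05)

    def test_plateau_above_half_level_undefined(self):
        t = np.arange(0, 300, 0.5)
        y = np.ones_like(t)
        y[t >= 50] = 5.0                # steps up, never decays
        tr = Trace(t, y, onset=30.0, normalized=True)
        times, amps = detect_spikes(tr)
        hd, dr = half_decay(tr, times, amps)
        assert hd is None and dr is None

    def test_no_spikes_undefined_not_exception(self):
        tr = make_trace(np.ones(600), normalized=True)
        hd, dr = half_decay(tr, np.array([]), np.array([]))
        assert hd is None and dr is None


class TestPopulation:
    def test_occurrence_arithmetic(self):
        traces = [planted([50, 100]) for _ in range(5)] + \
                 [planted([50]) for _ in range(4)]
        ms = analyze_population(traces)
        assert occurrence_rate(ms) == pytest.approx(100 * 5 / 9)

    def test_empty_population_raises(self):
        with pytest.raises(TraceError):
            occurrence_rate([])

    def test_undefined_metrics_excluded_from_summary(self):
        plateau_t = np.arange(0, 300, 0.5)
        y = np.ones_like(plateau_t)
        y[plateau_t >= 50] = 5.0
        traces = [planted([50.0], tau=10.0),
                  Trace(plateau_t, y, onset=30.0, normalized=True)]
        ms = analyze_population(traces)
        summary = population_summary(ms)
        assert summary["n_decay_defined"] == 1
        df = metrics_frame(ms)
        assert np.isnan(df.loc[1, "half_decay_s"])

    def test_csv_round_trip(self):
        traces = [planted([50, 90]), planted([60])]
        buf = io.StringIO()
        import pandas as pd
        df = pd.DataFrame({"time_s": traces[0].time,
                           "a": traces[0].signal, "b": traces[1].signal})
        df.to_csv(buf, index=False)
        buf.seek(0)
        back = read_trace_csv(buf, onset=30.0)
        m0 = analyze_trace(back[0])
        assert m0.oscillating and m0.n_spikes == 2


class TestSynchronizationIndex:
    def test_identical_trains(self):
        a = np.array([50.0, 100.0, 150.0])
        assert synchronization_index([a, a.copy()]) == pytest.approx(1.0)

    def test_disjoint_trains(self):
        a = np.array([50.0, 100.0])
        b = np.array([70.0, 120.0])
        assert synchronization_index([a, b], window_s=2.0) == pytest.approx(0.0)

    def test_without_spikes_undefined(self):
        assert synchronization_index([np.array([]), np.array([1.0])]) is None

    def test_poisson_chance_level(self):
        """Independent Poisson trains coincide at ≈ 1-exp(-2 r w) per spike."""
        rng = np.random.default_rng(7)
        rate, window, T = 0.02, 2.0, 5000.0
        vals = []
        for _ in range(40):
            a = np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
            b = np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
            si = synchronization_index([a, b], window_s=window)
            if si is not None:
                vals.append(si)
        expected = 1.0 - np.exp(-2 * rate * window)
        assert np.mean(vals) == pytest.approx(expected, abs=0.03)


class TestSamplingRobustness:
    def test_metrics_agree_across_1hz_2hz(self):
        """Same underlying trace sampled at 1 and 2 Hz: spike times within
        one sample, decay rates within 5%."""
        def sample(hz):
            t = np.arange(0, 300, 1.0 / hz)
            y = np.ones_like(t)
            for tp in (60.0, 140.0, 220.0):
                after = t >= tp
                y[after] += 4.0 * np.exp(-(t[after] - tp) / 15.0)
            return Trace(t, y, onset=30.0, normalized=True)

        m1 = analyze_trace(sample(1.0))
        m2 = analyze_trace(sample(2.0))
        assert m1.n_spikes == m2.n_spikes == 3
        assert np.allclose(m1.spike_times, m2.spike_times, atol=1.0)
        assert m1.decay_rate_per_s == pytest.approx(m2.decay_rate_per_s, rel=0.05)
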