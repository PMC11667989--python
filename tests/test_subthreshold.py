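from dataclasses import replace

import numpy as np
import pytest

import hvcephys as hv
from hvcephys import AnalysisParams, SpikeEvent
from hvcephys.subthreshold import SubthresholdTrace, motif_subthreshold
from hvcephys.synthetic import make_preset, psp_kernel, simulate_trial

from conftest import build_trial, spike_train_trace


class TestRemoveSpikes:
    def test_no_spikes_identity(self):
        trial = build_trial(np.sin(np.linspace(0, 20, 14_000)) - 65)
        st = hv.remove_spikes(trial, [])
        np.testing.assert_array_equal(st.voltage, trial.voltage)

    def test_single_spike_on_flat_baseline(self):
        v = spike_train_trace([0.3], spike_height=40.0)
        trial = build_trial(v)
        st = hv.remove_spikes(trial, hv.detect_spikes(trial))
        np.testing.assert_allclose(st.voltage, -65.0, atol=1e-9)

    def test_excision_completeness_on_simulation(self):
        tpl = make_preset("adult", 1)
        trial, _ = simulate_trial(tpl, 0, 1)
        spikes = hv.detect_spikes(trial)
        st = hv.remove_spikes(trial, spikes)
        thr = trial.voltage.mean() + AnalysisParams().spike_threshold
        assert st.voltage.max() < thr

    def test_excised_matches_spike_free_component(self):
        # ablation: same trial with and without spike waveforms
        tpl = make_preset("juvenile", 5)
        tpl_quiet = replace(tpl, n_burst_identities=0,
                            burst_times_percent=(), single_spike_rate=0.0)
        trial, truth = simulate_trial(tpl, 0, 5)
        spikes = hv.detect_spikes(trial)
        st = hv.remove_spikes(trial, spikes)
        outside = np.ones(trial.n_samples, dtype=bool)
        fs = trial.sampling_rate
        for t in truth.spike_times:
            i = int(t * fs)
            outside[max(0, i - int(0.02 * fs)):i + int(0.03 * fs)] = False
        rms = np.sqrt(np.mean(
            (st.voltage[outside] - trial.voltage[outside]) ** 2))
        assert rms < tpl.noise_sd  # excision leaves quiet samples untouched


class TestDemean:
    def test_constant_to_zero_and_idempotent(self):
        st = SubthresholdTrace(np.full(1000, -63.2), 20_000.0)
        d1 = hv.demean(st)
        np.testing.assert_allclose(d1.voltage, 0.0, atol=1e-12)
        rng = np.random.default_rng(0)
        st2 = SubthresholdTrace(rng.normal(-60, 2, 5000), 20_000.0)
        d2 = hv.demean(st2)
        np.testing.assert_allclose(hv.demean(d2).voltage, d2.voltage)
        assert abs(d2.voltage.mean()) < 1e-9 * d2.voltage.std()


class TestCorrelateZeroLag:
    def test_self_and_negation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 4000)
        assert hv.correlate_zero_lag(a, a) == pytest.approx(1.0)
        assert hv.correlate_zero_lag(a, -a) == pytest.approx(-1.0)

    def test_sine_cosine_orthogonal(self):
        t = np.linspace(0, 2 * np.pi, 10_001)[:-1]
        assert abs(hv.correlate_zero_lag(np.sin(t), np.cos(t))) < 1e-6

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b = rng.normal(0, 1, (2, 500))
            r = hv.correlate_zero_lag(a, b)
            assert r == pytest.approx(hv.correlate_zero_lag(b, a))
            assert -1.0 <= r <= 1.0

    def test_length_mismatch_resampled(self):
        t1 = np.linspace(0, 1, 1000)
        t2 = np.linspace(0, 1, 1300)
        r = hv.correlate_zero_lag(np.sin(8 * t1), np.sin(8 * t2))
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            hv.correlate_zero_lag(np.zeros(100), np.ones(100))


class TestStereotypy:
    def test_duplicated_trial_is_one(self):
        rng = np.random.default_rng(3)
        v = rng.normal(-65, 2, 14_000)
        trials = [build_trial(v, trial_index=i) for i in range(2)]
        assert hv.subthreshold_stereotypy(trials, [[], []]) \
            == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(4)
        trials = [build_trial(rng.normal(-65, 1, 14_000), trial_index=i)
                  for i in range(4)]
        val = hv.subthreshold_stereotypy(trials, [[]] * 4)
        assert abs(val) < 0.05

    def test_high_reliability_shared_template(self):
        tpl = make_preset("adult", 0)
        tpl = replace(tpl, burst_reliability=1.0, psp_locking=1.0,
                      n_burst_identities=3,
                      burst_times_percent=(20.0, 50.0, 75.0))
        trials, spt = [], []
        for k in range(5):
            trial, _ = simulate_trial(tpl, k, 0)
            trials.append(trial)
            spt.append(hv.detect_spikes(trial))
        assert hv.subthreshold_stereotypy(trials, spt) >= 0.8

    def test_needs_two_trials(self):
        trial = build_trial(np.zeros(14_000))
        with pytest.raises(ValueError):
            hv.subthreshold_stereotypy([trial], [[]])


def _psp_trace(amplitudes, times_s, fs=20_000.0, dur=1.0, tau_r=1.0,
               noise=0.0, seed=0):
    n = int(dur * fs)
    rng = np.random.default_rng(seed)
    v = np.full(n, -65.0) + rng.normal(0, noise, n)
    tail = np.arange(int(0.12 * fs)) / fs
    for a, t in zip(amplitudes, times_s):
        i = int(t * fs)
        k = psp_kernel(tail, a, tau_r, 5 * tau_r)
        v[i:i + k.size] += k[:n - i]
    return v


class TestDetectPSPs:
    def test_small_bump_rejected(self):
        v = _psp_trace([1.5], [0.5], noise=0.3)
        trial = build_trial(v, motif=(0.05, 0.95))
        st = SubthresholdTrace(v, 20_000.0)
        assert hv.detect_psps(st, trial) == []

    def test_flat_trace_no_events(self):
        trial = build_trial(np.full(20_000, -65.0), motif=(0.05, 0.95))
        st = SubthresholdTrace(trial.voltage, 20_000.0)
        assert hv.detect_psps(st, trial) == []

    def test_exactly_2mv_excluded(self):
        # "exceeding 2 mV" is strict: a noise-free 2.000 mV event is out
        v = _psp_trace([2.0, 4.0], [0.3, 0.6], noise=0.0)
        trial = build_trial(v, motif=(0.05, 0.95))
        events = hv.detect_psps(SubthresholdTrace(v, 20_000.0), trial)
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(0.6, abs=0.01)

    def test_known_kernels_recovered(self):
        times = [0.2, 0.4, 0.6, 0.8]
        v = _psp_trace([6.0] * 4, times, noise=0.3, seed=5)
        trial = build_trial(v, motif=(0.05, 0.95))
        events = hv.detect_psps(SubthresholdTrace(v, 20_000.0), trial)
        peaks = sorted(e.peak_time for e in events)
        assert len(peaks) == 4
        for t, e in zip(times, sorted(events, key=lambda e: e.peak_time)):
            assert abs(e.peak_time - (t + 0.0023)) < 1e-3  # kernel peak lag
            assert abs(e.amplitude - 6.0) / 6.0 < 0.1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        v = _psp_trace(rng.uniform(2.5, 8, 8),
                       np.sort(rng.uniform(0.1, 0.9, 8)), noise=0.5, seed=7)
        trial = build_trial(v, motif=(0.05, 0.95))
        st = SubthresholdTrace(v, 20_000.0)
        counts = [len(hv.detect_psps(st, trial,
                                     AnalysisParams(psp_min_amplitude=a)))
                  for a in (2.0, 3.0, 4.0, 6.0)]
        assert counts == sorted(counts, reverse=True)

    def test_events_on_excised_samples_discarded(self):
        v = _psp_trace([6.0], [0.5], noise=0.0)
        mask = np.zeros(v.size, dtype=bool)
        i_peak = int((0.5 + 0.0023) * 20_000)
        mask[i_peak - 100:i_peak + 100] = True
        trial = build_trial(v, motif=(0.05, 0.95))
        st = SubthresholdTrace(v, 20_000.0, excised=mask)
        assert hv.detect_psps(st, trial) == []


class TestPSPStats:
    def test_frequency_arithmetic(self):
        trial = build_trial(np.full(16_000, -65.0), fs=20_000.0,
                            motif=(0.05, 0.675))  # 0.625 s motif
        def ev(t):
            return hv.PSPEvent(onset_time=t - 0.002, peak_time=t,
                               amplitude=5.0, duration_ms=15.0)
        assert hv.psp_frequency([], trial) == 0.0
        events = [ev(0.06 + 0.07 * i) for i in range(8)]
        assert hv.psp_frequency(events, trial) == pytest.approx(12.8)
        events = [ev(0.06 + 0.06 * i) for i in range(10)]
        assert hv.psp_frequency(events, trial) == pytest.approx(16.0)

    def test_frequency_scales_with_count(self):
        trial = build_trial(np.full(16_000, -65.0), motif=(0.05, 0.65))
        def ev(t):
            return hv.PSPEvent(onset_time=t - 0.002, peak_time=t,
                               amplitude=5.0, duration_ms=15.0)
        f1 = hv.psp_frequency([ev(0.1)], trial)
        f3 = hv.psp_frequency([ev(0.1), ev(0.2), ev(0.3)], trial)
        assert f3 == pytest.approx(3 * f1)

    def test_duration_filter(self):
        mk = lambda d: hv.PSPEvent(onset_time=0.1, peak_time=0.105,
                                   amplitude=5.0, duration_ms=d)
        out = hv.psp_duration_stats([mk(20.0), mk(40.0)])
        assert out["mean_ms"] == pytest.approx(20.0)
        assert out["n"] == 1 and out["n_excluded"] == 1

    def test_all_excluded_undefined(self):
        mk = lambda d: hv.PSPEvent(onset_time=0.1, peak_time=0.105,
                                   amplitude=5.0, duration_ms=d)
        with pytest.raises(ValueError):
            hv.psp_duration_stats([mk(50.0)])
        with pytest.raises(ValueError):
            hv.psp_duration_stats([])
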