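from dataclasses import replace

import numpy as np
import pytest

import hvcephys as hv
from hvcephys import AnalysisParams, Burst
from hvcephys.burst_metrics import (burst_relative_rates, grand_mean_rate,
                                    preburst_stereotypy, spike_count_mode)
from hvcephys.synthetic import make_preset, simulate_trial

from conftest import build_trial


def _trials(n, motif=(0.05, 0.65)):
    return [build_trial(np.full(14_000, -65.0), motif=motif, trial_index=i)
            for i in range(n)]


def _burst_at(rel_ms, trial, n_spikes=3, isi_ms=4.0):
    t0 = trial.motif_onset + rel_ms / 1000.0
    return Burst(tuple(t0 + i * isi_ms / 1000.0 for i in range(n_spikes)),
                 trial_index=trial.trial_index)


class TestMatchRecurring:
    def test_chained_within_window(self):
        trials = _trials(3)
        bursts = [[_burst_at(100, trials[0])], [_burst_at(110, trials[1])],
                  [_burst_at(95, trials[2])]]
        groups, nonrec = hv.match_recurring(bursts, trials)
        assert len(groups) == 1 and nonrec == []
        assert len(groups[0].members) == 3
        assert groups[0].onset_times_relative_ms == pytest.approx(
            (100, 110, 95), abs=1e-6)

    def test_window_violation_nonrecurring(self):
        trials = _trials(2)
        bursts = [[_burst_at(100, trials[0])], [_burst_at(125, trials[1])]]
        groups, nonrec = hv.match_recurring(bursts, trials)
        assert groups == [] and len(nonrec) == 2

    def test_single_trial_no_groups(self):
        trials = _trials(1)
        groups, nonrec = hv.match_recurring([[_burst_at(50, trials[0])]],
                                            trials)
        assert groups == [] and len(nonrec) == 1

    def test_outputs_partition_bursts(self):
        trials = _trials(4)
        rng = np.random.default_rng(0)
        bursts = [[_burst_at(r, t) for r in rng.uniform(20, 500, 3)]
                  for t in trials]
        groups, nonrec = hv.match_recurring(bursts, trials)
        n_in = sum(len(b) for b in bursts)
        assert sum(len(g.members) for g in groups) + len(nonrec) == n_in

    def test_simulated_identities_recovered(self):
        tpl = make_preset("juvenile", 3)
        tpl = replace(tpl, burst_reliability=1.0, n_burst_identities=3,
                      burst_times_percent=(20.0, 45.0, 70.0))
        bursts, trials = [], []
        for k in range(5):
            trial, _ = simulate_trial(tpl, k, 3)
            bu, _ = hv.group_bursts(hv.detect_spikes(trial), trial)
            bursts.append(bu)
            trials.append(trial)
        groups, nonrec = hv.match_recurring(bursts, trials)
        assert len(groups) == 3 and nonrec == []
        assert all(len(g.members) == 5 for g in groups)
        assert all(g.reliability == 1.0 for g in groups)

    def test_shrinking_window_never_raises_fraction(self):
        trials = _trials(5)
        rng = np.random.default_rng(7)
        bursts = [[_burst_at(r, t) for r in
                   np.sort(rng.uniform(20, 500, rng.integers(1, 4)))]
                  for t in trials]
        all_b = [b for bu in bursts for b in bu]
        fracs = []
        for w in (40.0, 20.0, 10.0, 5.0, 2.0):
            groups, _ = hv.match_recurring(
                bursts, trials, AnalysisParams(recur_window=w))
            fracs.append(hv.recurring_fraction(groups, all_b))
        assert fracs == sorted(fracs, reverse=True)


class TestRecurringFraction:
    def test_paper_scale_arithmetic(self):
        trials = _trials(2)
        rec = [_burst_at(r, trials[0]) for r in np.arange(6) * 80 + 20]
        groups, _ = hv.match_recurring(
            [rec, [_burst_at((b.onset - trials[0].motif_onset) * 1000 + 5,
                             trials[1]) for b in rec]], trials)
        extra = [_burst_at(700, trials[0], n_spikes=2) for _ in range(8)]
        assert hv.recurring_fraction(groups, rec * 2 + extra) \
            == pytest.approx(12 / 20)

    def test_no_bursts_undefined(self):
        with pytest.raises(ValueError):
            hv.recurring_fraction([], [])


class TestDeltaSpikes:
    @pytest.mark.parametrize("counts, expected", [
        ((3, 3, 3), 0.0),
        ((3, 3, 4), 1 / 3),
        ((2, 4), 1.0),          # tie -> mode 2, |2-2|+|4-2| over 2
    ])
    def test_examples(self, counts, expected):
        trials = _trials(len(counts))
        members = tuple(
            (i, _burst_at(100, trials[i], n_spikes=c))
            for i, c in enumerate(counts))
        g = hv.RecurringBurstGroup(0, members, tuple([100.0] * len(counts)),
                                   len(counts))
        assert hv.delta_spikes(g) == pytest.approx(expected)
        assert g.mode_spikes == spike_count_mode(counts)

    def test_order_invariance_and_zero_iff_constant(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = tuple(rng.integers(2, 7, rng.integers(2, 8)))
            trials = _trials(len(counts))
            members = tuple((i, _burst_at(100, trials[i], n_spikes=c))
                            for i, c in enumerate(counts))
            g = hv.RecurringBurstGroup(0, members, tuple([100.0] * len(counts)),
                                       len(counts))
            perm = tuple(members[i] for i in rng.permutation(len(counts)))
            gp = hv.RecurringBurstGroup(0, perm, tuple([100.0] * len(counts)),
                                        len(counts))
            assert hv.delta_spikes(g) == pytest.approx(hv.delta_spikes(gp))
            assert (hv.delta_spikes(g) == 0) == (len(set(counts)) == 1)


class TestMaxBursts:
    def test_examples(self):
        trials = _trials(3)
        bursts = [[_burst_at(100, trials[0])],
                  [_burst_at(100, trials[1]), _burst_at(300, trials[1])], []]
        assert hv.max_bursts_per_motif(bursts, trials) == 2
        assert hv.max_bursts_per_motif([[], [], []], trials) == 0


class TestIFR:
    def test_two_spikes_4ms(self):
        b = Burst((0.1, 0.104))
        assert hv.instantaneous_firing_rate(b) == pytest.approx(250.0)

    def test_isis_3_and_5ms(self):
        b = Burst((0.1, 0.103, 0.108))
        assert hv.instantaneous_firing_rate(b) == pytest.approx(250.0)

    def test_boundary_formula(self):
        b = Burst((0.1, 0.110, 0.120))
        assert hv.instantaneous_firing_rate(b) == pytest.approx(100.0)

    def test_scale_consistency(self):
        b = Burst((0.1, 0.103, 0.108, 0.111))
        doubled = Burst(tuple(0.1 + 2 * (t - 0.1) for t in b.spike_times))
        assert hv.instantaneous_firing_rate(doubled) == pytest.approx(
            hv.instantaneous_firing_rate(b) / 2)


class TestProgression:
    def test_single_burst_trajectory(self):
        b = Burst((0.0, 0.004, 0.009))
        means, counts = hv.ifr_progression([b])
        assert means == pytest.approx([250.0, 200.0])
        assert counts.tolist() == [1, 1]

    def test_seven_spike_burst_excluded(self):
        b7 = Burst(tuple(np.arange(7) * 0.004))
        means, counts = hv.ifr_progression([b7])
        assert means.size == 0

    def test_mean_across_bursts(self):
        bursts = [Burst((0.0, 0.004)), Burst((0.0, 0.006))]
        means, counts = hv.ifr_progression(bursts)
        assert means == pytest.approx([(250.0 + 1000 / 6) / 2])

    def test_relative_progression_centering(self):
        traj = np.array([250.0, 200.0])
        assert hv.relative_progression(traj, 225.0) == pytest.approx(
            [25.0, -25.0])

    def test_centering_on_own_mean_sums_to_zero(self):
        rng = np.random.default_rng(3)
        bursts = [Burst(tuple(np.cumsum(np.r_[0.1, rng.uniform(2e-3, 8e-3,
                                                               n)])))
                  for n in rng.integers(1, 6, 15)]
        means, counts = hv.ifr_progression(bursts)
        gm = grand_mean_rate(bursts)
        centered = hv.relative_progression(means, gm)
        assert float(np.sum(centered * counts)) == pytest.approx(0.0, abs=1e-6)

    def test_burst_relative_rates_reference(self):
        bursts = [Burst((0.0, 0.004, 0.009))]
        ref = np.array([250.0, 200.0])
        assert burst_relative_rates(bursts, ref) == pytest.approx([0.0])


class TestPreburst:
    def test_early_burst_skipped_with_warning(self):
        trial = build_trial(np.full(14_000, -65.0), motif=(0.005, 0.6))
        b = Burst((0.010, 0.014))
        with pytest.warns(UserWarning):
            assert hv.preburst_windows(trial, b) is None

    def test_flat_baseline_zero_after_demeaning(self):
        trial = build_trial(np.full(14_000, -65.0))
        b = Burst((0.3, 0.304))
        seg = hv.preburst_windows(trial, b)
        assert seg.size == int(0.015 * trial.sampling_rate)
        np.testing.assert_allclose(seg, 0.0, atol=1e-12)

    def test_identical_drive_correlates_near_one(self):
        # two bursts preceded by the same PSP-like rise
        fs = 20_000.0
        v = np.full(20_000, -65.0)
        ramp = np.linspace(0, 6, int(0.015 * fs))
        for t0 in (0.3, 0.6):
            i = int(t0 * fs)
            v[i - ramp.size:i] += ramp
        trial = build_trial(v, motif=(0.05, 0.9))
        segs = [hv.preburst_windows(trial, Burst((t0, t0 + 0.004)))
                for t0 in (0.3, 0.6)]
        assert preburst_stereotypy(segs) == pytest.approx(1.0, abs=1e-6)

    def test_stereotypy_extremes(self):
        a = np.sin(np.linspace(0, 6, 300))
        assert preburst_stereotypy([a, a]) == pytest.approx(1.0)
        assert preburst_stereotypy([a, -a]) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            preburst_stereotypy([a])

    def test_high_reliability_neuron_stereotyped(self):
        tpl = make_preset("adult", 2)
        tpl = replace(tpl, burst_reliability=1.0, n_burst_identities=2,
                      burst_times_percent=(30.0, 70.0))
        segs = []
        for k in range(5):
            trial, _ = simulate_trial(tpl, k, 2)
            sp = hv.detect_spikes(trial)
            bursts, _ = hv.group_bursts(sp, trial)
            for b in bursts:
                seg = hv.preburst_windows(trial, b, spikes=sp)
                if seg is not None:
                    segs.append(seg)
        assert preburst_stereotypy(segs) >= 0.8
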