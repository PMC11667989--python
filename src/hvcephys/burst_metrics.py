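"""Burst statistics across motif renditions.

Covers recurring-burst matching (+/-20 ms onset chaining across
consecutive trials), spike-count stability of recurring bursts
(delta-spikes relative to the modal count), instantaneous firing rate and
its within-burst progression, and the stereotypy of the subthreshold
voltage in the 15 ms preceding each burst.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import subthreshold as _sub
from .event_detection import Burst, SpikeEvent
from .trace_model import AnalysisParams, TrialRecording

__all__ = [
    "RecurringBurstGroup",
    "delta_spikes",
    "grand_mean_rate",
    "ifr_progression",
    "instantaneous_firing_rate",
    "match_recurring",
    "max_bursts_per_motif",
    "preburst_stereotypy",
    "preburst_windows",
    "recurring_fraction",
    "relative_progression",
    "spike_count_mode",
]


@dataclass(frozen=True)
class RecurringBurstGroup:
    """One burst identity chained across >=2 motif renditions.

    ``members`` holds ``(trial_index, Burst)`` pairs, at most one per
    trial; consecutive members' motif-relative onsets differ by at most
    the recurrence window.
    """

    identity_id: int
    members: tuple            # ((trial_index, Burst), ...)
    onset_times_relative_ms: tuple
    n_trials_analyzed: int

    @property
    def spike_counts(self) -> tuple:
        return tuple(b.n_spikes for _, b in self.members)

    @property
    def mode_spikes(self) -> int:
        return spike_count_mode(self.spike_counts)

    @property
    def delta_spikes(self) -> float:
        return delta_spikes(self)

    @property
    def reliability(self) -> float:
        return len(self.members) / self.n_trials_analyzed


def spike_count_mode(counts: Sequence[int]) -> int:
    """Most frequent spike count; ties broken toward the smallest count."""
    freq = Counter(counts)
    best = max(freq.values())
    return min(c for c, f in freq.items() if f == best)


def delta_spikes(group: RecurringBurstGroup) -> float:
    """Mean absolute deviation of member spike counts from their mode."""
    counts = group.spike_counts
    if len(counts) < 2:
        raise ValueError("delta_spikes needs >= 2 member bursts")
    mode = spike_count_mode(counts)
    return float(np.mean([abs(c - mode) for c in counts]))


def _relative_onset_ms(burst: Burst, trial: TrialRecording) -> float:
    return (burst.onset - trial.motif_onset) * 1000.0


def match_recurring(bursts_by_trial: Sequence[Sequence[Burst]],
                    trials: Sequence[TrialRecording],
                    params: AnalysisParams | None = None,
                    ) -> tuple[list[RecurringBurstGroup], list[Burst]]:
    """Chain bursts across consecutive trials into recurring identities.

    A burst in trial t+1 joins a group when its motif-relative onset lies
    within +/-recur_window (20 ms) of the group's trial-t member onset;
    at most one burst per trial per group (nearest onset wins; exact
    distance ties go to the earlier-onset burst).  Groups spanning >= 2
    trials are recurring; all other bursts are returned as nonrecurring.
    The two outputs partition the input bursts.
    """
    params = params or AnalysisParams()
    if len(bursts_by_trial) != len(trials):
        raise ValueError("bursts_by_trial and trials must align")
    order = np.argsort([tr.trial_index for tr in trials])
    n_trials = len(trials)
    window = params.recur_window

    # open chain: list of (trial_pos, burst, rel_onset_ms) tuples
    open_chains: list[list[tuple[int, Burst, float]]] = []
    closed: list[list[tuple[int, Burst, float]]] = []

    for pos, oi in enumerate(order):
        trial = trials[oi]
        entries = [(b, _relative_onset_ms(b, trial))
                   for b in sorted(bursts_by_trial[oi], key=lambda b: b.onset)]
        active = [c for c in open_chains if c[-1][0] == pos - 1]
        stale = [c for c in open_chains if c[-1][0] < pos - 1]
        closed.extend(stale)
        # candidate (distance, burst onset, chain idx, burst idx) pairs
        cands = []
        for ci, chain in enumerate(active):
            last_onset = chain[-1][2]
            for bi, (b, rel) in enumerate(entries):
                d = abs(rel - last_onset)
                if d <= window:
                    cands.append((d, rel, ci, bi))
        cands.sort()
        used_chain: set[int] = set()
        used_burst: set[int] = set()
        for d, rel, ci, bi in cands:
            if ci in used_chain or bi in used_burst:
                continue
            active[ci].append((pos, entries[bi][0], entries[bi][1]))
            used_chain.add(ci)
            used_burst.add(bi)
        closed.extend(c for ci, c in enumerate(active) if ci not in used_chain)
        open_chains = [c for ci, c in enumerate(active) if ci in used_chain]
        for bi, (b, rel) in enumerate(entries):
            if bi not in used_burst:
                open_chains.append([(pos, b, rel)])
    closed.extend(open_chains)

    groups: list[RecurringBurstGroup] = []
    nonrecurring: list[Burst] = []
    gid = 0
    for chain in closed:
        if len(chain) >= 2:
            groups.append(RecurringBurstGroup(
                identity_id=gid,
                members=tuple((trials[order[p]].trial_index, b)
                              for p, b, _ in chain),
                onset_times_relative_ms=tuple(r for _, _, r in chain),
                n_trials_analyzed=n_trials,
            ))
            gid += 1
        else:
            nonrecurring.extend(b for _, b, _ in chain)
    groups.sort(key=lambda g: g.onset_times_relative_ms[0])
    groups = [RecurringBurstGroup(i, g.members, g.onset_times_relative_ms,
                                  g.n_trials_analyzed)
              for i, g in enumerate(groups)]
    return groups, nonrecurring


def recurring_fraction(groups: Sequence[RecurringBurstGroup],
                       all_bursts: Sequence[Burst]) -> float:
    """Fraction of all bursts that belong to a recurring identity."""
    if len(all_bursts) == 0:
        raise ValueError("no bursts: recurring fraction undefined")
    n_rec = sum(len(g.members) for g in groups)
    return n_rec / len(all_bursts)


def max_bursts_per_motif(bursts_by_trial: Sequence[Sequence[Burst]],
                         trials: Sequence[TrialRecording]) -> int:
    """Maximum over trials of the number of bursts starting within the motif."""
    counts = [sum(1 for b in bursts if trial.in_motif(b.onset))
              for bursts, trial in zip(bursts_by_trial, trials)]
    return max(counts, default=0)


def instantaneous_firing_rate(burst: Burst) -> float:
    """IFR of one burst: number of ISIs divided by their summed duration.

    Equals the reciprocal of the mean inter-spike interval, in Hz.
    """
    return burst.ifr_hz


def ifr_progression(bursts: Sequence[Burst],
                    params: AnalysisParams | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-ISI rate trajectory across bursts of 2..6 spikes.

    The i-th entry is the mean of 1/ISI_i over all qualifying bursts that
    have an i-th interval; returns ``(means_hz, counts)``, each of length
    equal to the longest qualifying burst's ISI count (at most 5).
    """
    params = params or AnalysisParams()
    kept = [b for b in bursts if 2 <= b.n_spikes <= params.progression_max_spikes]
    if not kept:
        return np.array([]), np.array([], dtype=int)
    max_isis = max(b.n_spikes - 1 for b in kept)
    sums = np.zeros(max_isis)
    counts = np.zeros(max_isis, dtype=int)
    for b in kept:
        rates = 1.0 / b.isis_s
        sums[:rates.size] += rates
        counts[:rates.size] += 1
    return sums / counts, counts


def grand_mean_rate(bursts: Sequence[Burst],
                    params: AnalysisParams | None = None) -> float:
    """Count-weighted mean of all per-ISI rates of qualifying bursts (Hz)."""
    means, counts = ifr_progression(bursts, params)
    if means.size == 0:
        raise ValueError("no qualifying bursts")
    return float(np.sum(means * counts) / np.sum(counts))


def relative_progression(trajectory: np.ndarray,
                         group_mean_rate: float) -> np.ndarray:
    """Center a per-ISI rate trajectory on a group grand-mean rate."""
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.size == 0:
        raise ValueError("empty trajectory")
    return trajectory - group_mean_rate


def burst_relative_rates(bursts: Sequence[Burst],
                         reference: np.ndarray,
                         params: AnalysisParams | None = None) -> list[float]:
    """Per-burst mean deviation of per-ISI rates from a reference trajectory.

    ``reference`` is a per-ISI-index mean trajectory (e.g. the group's own
    from :func:`ifr_progression`, or another group's for a cross-group
    comparison).  One scalar per qualifying burst.
    """
    params = params or AnalysisParams()
    reference = np.asarray(reference, dtype=float)
    out: list[float] = []
    for b in bursts:
        if not 2 <= b.n_spikes <= params.progression_max_spikes:
            continue
        rates = 1.0 / b.isis_s
        k = min(rates.size, reference.size)
        if k == 0:
            continue
        out.append(float(np.mean(rates[:k] - reference[:k])))
    return out


def preburst_windows(trial: TrialRecording, burst: Burst,
                     params: AnalysisParams | None = None,
                     spikes: Sequence[SpikeEvent] | None = None,
                     ) -> np.ndarray | None:
    """Spike-excised, demeaned voltage over the 15 ms before burst onset.

    Returns ``None`` (with a warning) when the burst starts too early in
    the trace for a full window.  ``spikes`` defaults to the burst's own
    spikes; pass the trial's full spike list for proper excision of
    neighbouring activity.
    """
    params = params or AnalysisParams()
    fs = trial.sampling_rate
    win_s = params.preburst_window / 1000.0
    if burst.onset - win_s < 0:
        warnings.warn("burst onset precedes a full pre-burst window; skipped")
        return None
    if spikes is None:
        spikes = [SpikeEvent(peak_time=t, peak_voltage=np.nan,
                             trial_index=trial.trial_index)
                  for t in burst.spike_times]
    sub = _sub.remove_spikes(trial, spikes, params).voltage
    i1 = int(round(burst.onset * fs))
    i0 = i1 - int(round(win_s * fs))
    seg = sub[i0:i1]
    return seg - seg.mean()


def preburst_stereotypy(segments: Sequence[np.ndarray]) -> float:
    """Mean pairwise zero-lag correlation of a neuron's pre-burst windows."""
    segs = [s for s in segments if s is not None]
    if len(segs) < 2:
        raise ValueError("pre-burst stereotypy needs >= 2 segments")
    vals = [_sub.correlate_zero_lag(segs[i], segs[j])
            for i in range(len(segs)) for j in range(i + 1, len(segs))]
    return float(np.mean(vals))
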