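"""Spike detection and burst grouping on single-trial voltage traces.

Spikes are suprathreshold excursions above the whole-trial mean voltage
plus a fixed threshold (15 mV by default), one peak per contiguous
excursion.  Bursts are maximal chains of >=2 consecutive spikes whose
adjacent-spike rate strictly exceeds 100 Hz *and* which ride the same
membrane depolarization event — operationalized as the spike-excised
voltage between the two peaks never dropping below the trace mean plus a
configurable floor (5 mV default).  Everything not in a burst is a
single spike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import subthreshold as _sub
from .trace_model import AnalysisParams, TrialRecording

__all__ = [
    "Burst",
    "SpikeEvent",
    "detect_spikes",
    "group_bursts",
    "single_spikes_per_motif",
    "spikes_per_motif",
]

#: Minimum spike peak separation (absolute refractory guard), ms.
MIN_PEAK_SEPARATION_MS = 1.0


@dataclass(frozen=True)
class SpikeEvent:
    peak_time: float       # seconds from trace start
    peak_voltage: float    # mV
    trial_index: int = 0


@dataclass(frozen=True)
class Burst:
    """A group of >=2 spikes with adjacent rates above the burst criterion."""

    spike_times: tuple
    trial_index: int = 0

    def __post_init__(self) -> None:
        st = tuple(float(t) for t in self.spike_times)
        object.__setattr__(self, "spike_times", st)
        if len(st) < 2:
            raise ValueError("a burst needs >= 2 spikes")
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("burst spike times must be strictly increasing")

    @property
    def onset(self) -> float:
        """Burst onset = time of the first spike (seconds)."""
        return self.spike_times[0]

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def duration_ms(self) -> float:
        """Last spike peak minus first spike peak, ms."""
        return (self.spike_times[-1] - self.spike_times[0]) * 1000.0

    @property
    def isis_s(self) -> np.ndarray:
        return np.diff(np.asarray(self.spike_times))

    @property
    def ifr_hz(self) -> float:
        """Instantaneous firing rate: number of ISIs over their sum."""
        return float(len(self.isis_s) / self.isis_s.sum())


def detect_spikes(trial: TrialRecording,
                  params: AnalysisParams | None = None) -> list[SpikeEvent]:
    """Detect spikes as peaks of excursions above mean + spike_threshold.

    One spike per contiguous suprathreshold excursion; peaks closer than
    1 ms are merged keeping the taller one.
    """
    params = params or AnalysisParams()
    v = trial.voltage
    thr = float(v.mean()) + params.spike_threshold
    above = v > thr
    if not above.any():
        return []
    # contiguous suprathreshold runs -> one peak (argmax) each
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, v.size]
    peaks = [int(lo + np.argmax(v[lo:hi])) for lo, hi in zip(starts, ends)]
    # refractory guard: merge peaks closer than 1 ms, keep the taller
    min_sep = MIN_PEAK_SEPARATION_MS * 1e-3 * trial.sampling_rate
    kept: list[int] = []
    for p in peaks:
        if kept and (p - kept[-1]) < min_sep:
            if v[p] > v[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    fs = trial.sampling_rate
    return [SpikeEvent(peak_time=p / fs, peak_voltage=float(v[p]),
                       trial_index=trial.trial_index) for p in kept]


def group_bursts(spikes: Sequence[SpikeEvent], trial: TrialRecording,
                 params: AnalysisParams | None = None,
                 ) -> tuple[list[Burst], list[SpikeEvent]]:
    """Partition spikes into bursts and single spikes.

    Consecutive spikes chain into one burst iff their ISI is strictly
    below 1/burst_rate_min (an adjacent rate strictly above 100 Hz) and
    the spike-excised voltage between the two peaks never falls below
    the trace mean + depolarization_floor.  Maximal chains of >=2 spikes
    are bursts; every spike lands in exactly one output list.
    """
    params = params or AnalysisParams()
    spikes = sorted(spikes, key=lambda s: s.peak_time)
    if not spikes:
        return [], []
    fs = trial.sampling_rate
    mean_v = float(trial.voltage.mean())
    floor = mean_v + params.depolarization_floor
    max_isi = 1.0 / params.burst_rate_min
    sub = _sub.remove_spikes(trial, spikes, params).voltage

    def joinable(a: SpikeEvent, b: SpikeEvent) -> bool:
        isi = b.peak_time - a.peak_time
        # strict "exceeds 100 Hz": an ISI at exactly 1/burst_rate_min must
        # not join; the relative guard absorbs float error in peak times
        if not isi < max_isi * (1.0 - 1e-9):
            return False
        i0 = int(round(a.peak_time * fs))
        i1 = int(round(b.peak_time * fs)) + 1
        return bool(sub[i0:i1].min() >= floor)

    bursts: list[Burst] = []
    singles: list[SpikeEvent] = []
    chain = [spikes[0]]
    for prev, cur in zip(spikes, spikes[1:]):
        if joinable(prev, cur):
            chain.append(cur)
        else:
            if len(chain) >= 2:
                bursts.append(Burst(tuple(s.peak_time for s in chain),
                                    trial_index=trial.trial_index))
            else:
                singles.extend(chain)
            chain = [cur]
    if len(chain) >= 2:
        bursts.append(Burst(tuple(s.peak_time for s in chain),
                            trial_index=trial.trial_index))
    else:
        singles.extend(chain)
    return bursts, singles


def spikes_per_motif(trial: TrialRecording,
                     spikes: Sequence[SpikeEvent]) -> int:
    """Number of spikes whose peak lies within the motif window."""
    return sum(1 for s in spikes if trial.in_motif(s.peak_time))


def single_spikes_per_motif(trial: TrialRecording,
                            singles: Sequence[SpikeEvent]) -> int:
    """Number of non-burst spikes within the motif window."""
    return spikes_per_motif(trial, singles)
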