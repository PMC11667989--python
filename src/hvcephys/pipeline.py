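"""End-to-end per-neuron analysis: detection through feature summary.

`summarize_neuron` runs the full chain on one neuron's motif renditions —
spike detection, burst grouping, recurring-burst matching, firing-rate
and progression metrics, pre-burst and whole-motif subthreshold
stereotypy, PSP detection — and packs the result into a
:class:`~hvcephys.group_stats.NeuronSummary` ready for the cohort
comparison battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import burst_metrics as bm
from . import event_detection as ed
from . import subthreshold as sub
from .group_stats import NeuronSummary
from .trace_model import AnalysisParams, TrialRecording, read_neuron_dir

__all__ = ["NeuronDetections", "detect_neuron", "summarize_neuron",
           "summarize_neuron_dir"]


@dataclass
class NeuronDetections:
    """Intermediate per-trial detections for one neuron."""

    trials: list
    spikes: list          # list per trial of SpikeEvent
    bursts: list          # list per trial of Burst
    singles: list         # list per trial of SpikeEvent
    groups: list = field(default_factory=list)
    nonrecurring: list = field(default_factory=list)


def detect_neuron(trials: Sequence[TrialRecording],
                  params: AnalysisParams | None = None) -> NeuronDetections:
    """Run spike detection, burst grouping and recurrence matching."""
    params = params or AnalysisParams()
    trials = sorted(trials, key=lambda t: t.trial_index)
    spikes, bursts, singles = [], [], []
    for trial in trials:
        sp = ed.detect_spikes(trial, params)
        bu, si = ed.group_bursts(sp, trial, params)
        spikes.append(sp)
        bursts.append(bu)
        singles.append(si)
    det = NeuronDetections(trials=list(trials), spikes=spikes,
                           bursts=bursts, singles=singles)
    det.groups, det.nonrecurring = bm.match_recurring(bursts, trials, params)
    return det


def summarize_neuron(trials: Sequence[TrialRecording],
                     params: AnalysisParams | None = None,
                     detections: NeuronDetections | None = None,
                     ) -> NeuronSummary:
    """Compute the full feature vector of one neuron."""
    params = params or AnalysisParams()
    det = detections or detect_neuron(trials, params)
    trials = det.trials
    first = trials[0]
    all_bursts = [b for bu in det.bursts for b in bu]

    summary = NeuronSummary(
        neuron_id=first.neuron_id,
        age_group=first.age_group,
        projection_class=first.projection_class,
        n_trials=len(trials),
        max_bursts=bm.max_bursts_per_motif(det.bursts, trials),
        mean_spikes_per_motif=float(np.mean(
            [ed.spikes_per_motif(t, sp) for t, sp in zip(trials, det.spikes)])),
        mean_single_spikes_per_motif=float(np.mean(
            [ed.single_spikes_per_motif(t, si)
             for t, si in zip(trials, det.singles)])),
        mean_burst_spikes_per_motif=float(np.mean(
            [sum(b.n_spikes for b in bu if t.in_motif(b.onset))
             for t, bu in zip(trials, det.bursts)])),
        spikes_per_burst=[b.n_spikes for b in all_bursts],
        burst_ifrs=[bm.instantaneous_firing_rate(b) for b in all_bursts],
        burst_durations_ms=[b.duration_ms for b in all_bursts],
        delta_spikes_values=[bm.delta_spikes(g) for g in det.groups],
        recurring_count=sum(len(g.members) for g in det.groups),
        total_bursts=len(all_bursts),
    )
    means, counts = bm.ifr_progression(all_bursts, params)
    summary.progression_means = means.tolist()
    summary.progression_counts = counts.tolist()

    # pre-burst stereotypy over all bursts of the neuron
    segments = []
    for trial, sp, bu in zip(trials, det.spikes, det.bursts):
        for b in bu:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                seg = bm.preburst_windows(trial, b, params, spikes=sp)
            if seg is not None:
                segments.append(seg)
    if len(segments) >= 2:
        summary.preburst_stereotypy = bm.preburst_stereotypy(segments)

    if len(trials) >= 2:
        summary.subthreshold_stereotypy = sub.subthreshold_stereotypy(
            trials, det.spikes, params)

    # PSP statistics, pooled over trials
    amps: list[float] = []
    durs: list[float] = []
    freqs: list[float] = []
    for trial, sp in zip(trials, det.spikes):
        st = sub.remove_spikes(trial, sp, params)
        events = sub.detect_psps(st, trial, params)
        in_motif = [e for e in events if trial.in_motif(e.peak_time)]
        amps.extend(e.amplitude for e in in_motif)
        durs.extend(e.duration_ms for e in in_motif
                    if e.duration_ms < params.psp_max_duration)
        freqs.append(sub.psp_frequency(events, trial))
    summary.psp_amplitudes = amps
    summary.psp_durations_ms = durs
    summary.psp_frequency = float(np.mean(freqs)) if freqs else None
    return summary


def summarize_neuron_dir(neuron_dir: Path | str,
                         params: AnalysisParams | None = None) -> NeuronSummary:
    """Read a neuron directory and summarize it."""
    return summarize_neuron(read_neuron_dir(neuron_dir), params)
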