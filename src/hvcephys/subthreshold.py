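"""Subthreshold analysis: spike excision, PSP detection, trace stereotypy.

The subthreshold membrane potential carries the synaptic drive a neuron
receives.  Analysis proceeds by cutting out spikes (linear interpolation
across a short window around each peak), demeaning, and then either
(a) correlating traces across motif renditions at zero lag — the
*subthreshold stereotypy* of a neuron — or (b) detecting depolarizing
postsynaptic-potential (PSP) events whose trough-to-peak amplitude
strictly exceeds 2 mV, and summarizing their amplitude, duration and
frequency (events per motif duration).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .trace_model import AnalysisParams, TrialRecording

__all__ = [
    "PSPEvent",
    "SubthresholdTrace",
    "correlate_zero_lag",
    "demean",
    "detect_psps",
    "psp_frequency",
    "psp_duration_stats",
    "remove_spikes",
    "subthreshold_stereotypy",
]


@dataclass(frozen=True)
class SubthresholdTrace:
    """A voltage trace with spikes excised (and optionally demeaned).

    ``excised`` marks the samples that were replaced by interpolation;
    PSP events whose peak falls on an excised sample are untrustworthy
    and are discarded by :func:`detect_psps`.
    """

    voltage: np.ndarray
    sampling_rate: float
    demeaned: bool = False
    excised: np.ndarray | None = None
    source: TrialRecording | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "voltage", np.asarray(self.voltage, float))
        if self.excised is None:
            object.__setattr__(
                self, "excised", np.zeros(self.voltage.size, dtype=bool))


@dataclass(frozen=True)
class PSPEvent:
    """A depolarizing subthreshold event.

    Amplitude is trough-to-peak: the voltage at the peak minus the voltage
    at the preceding local minimum (the onset).  Duration runs from onset
    until the voltage first returns to the onset level, or to the next
    local minimum, whichever comes first.
    """

    onset_time: float
    peak_time: float
    amplitude: float
    duration_ms: float

    def __post_init__(self) -> None:
        if not self.onset_time < self.peak_time:
            raise ValueError("PSP onset must precede its peak")
        if self.duration_ms <= 0:
            raise ValueError("PSP duration must be positive")


def _spike_windows(peak_indices: np.ndarray, n: int, fs: float,
                   pre_ms: float, post_ms: float) -> list[tuple[int, int]]:
    """Merged half-open excision windows [lo, hi) around spike peaks."""
    pre = int(round(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    raw = sorted((max(0, p - pre), min(n, p + post + 1)) for p in peak_indices)
    merged: list[tuple[int, int]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def remove_spikes(trial: TrialRecording, spikes: Sequence,
                  params: AnalysisParams | None = None,
                  window_pre: float | None = None,
                  window_post: float | None = None) -> SubthresholdTrace:
    """Excise spikes by linear interpolation across a window around each peak.

    Samples within [peak - 2 ms, peak + 5 ms] (defaults) are replaced by a
    straight line between the window endpoints; overlapping windows are
    merged first.  Each endpoint anchor is a short (0.3 ms) mean of the
    samples just outside the window, so a single noisy boundary sample
    cannot tilt the interpolated segment.  Output length equals input
    length.
    """
    params = params or AnalysisParams()
    pre = params.spike_cut_pre if window_pre is None else window_pre
    post = params.spike_cut_post if window_post is None else window_post
    v = trial.voltage.copy()
    n = v.size
    fs = trial.sampling_rate
    anchor = max(1, int(round(0.3e-3 * fs)))
    peaks = np.array([int(round(s.peak_time * fs)) for s in spikes], dtype=int)
    mask = np.zeros(n, dtype=bool)
    for lo, hi in _spike_windows(peaks, n, fs, pre, post):
        if lo > 0:
            left = float(v[max(0, lo - anchor):lo].mean())
        else:
            left = float(v[hi:min(n, hi + anchor)].mean()) if hi < n else float(v[-1])
        right = float(v[hi:min(n, hi + anchor)].mean()) if hi < n else left
        v[lo:hi] = np.linspace(left, right, hi - lo + 2)[1:-1]
        mask[lo:hi] = True
    return SubthresholdTrace(voltage=v, sampling_rate=fs, excised=mask,
                             source=trial)


def demean(trace: SubthresholdTrace) -> SubthresholdTrace:
    """Subtract the mean voltage; idempotent."""
    return replace(trace, voltage=trace.voltage - trace.voltage.mean(),
                   demeaned=True)


def _as_array(x) -> np.ndarray:
    return x.voltage if isinstance(x, SubthresholdTrace) else np.asarray(x, float)


def correlate_zero_lag(a, b) -> float:
    """Normalized zero-lag cross-correlation of two demeaned traces.

    If lengths differ (motif tempo variability), both are linearly
    resampled onto the shorter length.  Raises on zero-variance input.
    """
    va, vb = _as_array(a), _as_array(b)
    if va.size != vb.size:
        m = min(va.size, vb.size)
        grid = np.linspace(0.0, 1.0, m)
        va = np.interp(grid, np.linspace(0.0, 1.0, va.size), va)
        vb = np.interp(grid, np.linspace(0.0, 1.0, vb.size), vb)
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-variance trace: correlation undefined")
    return float(np.dot(va, vb) / (na * nb))


def motif_subthreshold(trial: TrialRecording, spikes: Sequence,
                       params: AnalysisParams | None = None) -> SubthresholdTrace:
    """Spike-excised, demeaned subthreshold voltage over the motif window."""
    st = remove_spikes(trial, spikes, params)
    sl = trial.motif_slice()
    seg = SubthresholdTrace(voltage=st.voltage[sl],
                            sampling_rate=trial.sampling_rate,
                            excised=st.excised[sl], source=trial)
    return demean(seg)


def subthreshold_stereotypy(trials: Sequence[TrialRecording],
                            spikes_per_trial: Sequence[Sequence],
                            params: AnalysisParams | None = None) -> float:
    """Mean pairwise zero-lag correlation of motif-window subthreshold traces.

    Each trial is spike-excised, restricted to the motif window and
    demeaned; every unordered pair of trials contributes one correlation.
    """
    if len(trials) < 2:
        raise ValueError("stereotypy needs >= 2 trials")
    segs = [motif_subthreshold(tr, sp, params)
            for tr, sp in zip(trials, spikes_per_trial)]
    vals = [correlate_zero_lag(segs[i], segs[j])
            for i in range(len(segs)) for j in range(i + 1, len(segs))]
    return float(np.mean(vals))


def _lowpass(v: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff >= nyq:
        return v
    b, a = signal.butter(4, cutoff / nyq, btype="low")
    return signal.filtfilt(b, a, v)


def detect_psps(trace: SubthresholdTrace, trial: TrialRecording,
                params: AnalysisParams | None = None) -> list[PSPEvent]:
    """Detect depolarizing PSP events on a spike-excised trace.

    Peak candidacy uses a low-pass filtered copy (default 200 Hz cutoff);
    amplitudes are measured on the unsmoothed trace as the difference of
    short windowed means (+/-0.5 ms) at the peak and at the preceding
    local minimum (the onset), which keeps single-sample noise out of the
    trough-to-peak estimate.  Events are kept when the amplitude strictly
    exceeds ``psp_min_amplitude`` and the peak is not on an excised sample.
    """
    params = params or AnalysisParams()
    v = trace.voltage
    fs = trace.sampling_rate
    smooth = _lowpass(v, fs, params.psp_lowpass_hz)
    # candidate peaks need a little prominence on the smoothed trace so
    # residual noise ripples riding a decay do not split one event in two
    peaks, _ = signal.find_peaks(smooth, prominence=0.5)
    troughs, _ = signal.find_peaks(-smooth)
    if peaks.size == 0 or troughs.size == 0:
        return []
    half = max(1, int(round(0.5e-3 * fs)))

    def windowed(i: int) -> float:
        return float(v[max(0, i - half):min(v.size, i + half + 1)].mean())

    events: list[PSPEvent] = []
    for pk in peaks:
        j = np.searchsorted(troughs, pk) - 1
        if j < 0:
            continue
        onset = int(troughs[j])
        amp = windowed(pk) - windowed(onset)
        if not amp > params.psp_min_amplitude:
            continue
        if trace.excised is not None and trace.excised[pk]:
            continue
        # duration endpoint: return to onset level, or next trough
        level = smooth[onset]
        after = smooth[pk:]
        below = np.nonzero(after <= level)[0]
        end_cross = pk + int(below[0]) if below.size else v.size - 1
        nxt = np.searchsorted(troughs, pk)
        end_trough = int(troughs[nxt]) if nxt < troughs.size else v.size - 1
        end = min(end_cross, end_trough)
        dur_ms = (end - onset) / fs * 1000.0
        if dur_ms <= 0:
            continue
        events.append(PSPEvent(onset_time=onset / fs, peak_time=pk / fs,
                               amplitude=amp, duration_ms=dur_ms))
    return events


def psp_frequency(events: Sequence[PSPEvent], trial: TrialRecording) -> float:
    """PSP event rate: in-motif event count over motif duration (Hz)."""
    n = sum(1 for e in events if trial.in_motif(e.peak_time))
    return n / (trial.motif_offset - trial.motif_onset)


def psp_duration_stats(events: Sequence[PSPEvent],
                       params: AnalysisParams | None = None) -> dict:
    """Summarize PSP durations after excluding implausibly long events.

    Durations at or above ``psp_max_duration`` (default 35 ms) are dropped
    before summarizing; the excluded count is reported.  Raises when no
    event survives (an undefined summary, not a zero).
    """
    params = params or AnalysisParams()
    durs = np.array([e.duration_ms for e in events], dtype=float)
    kept = durs[durs < params.psp_max_duration]
    if kept.size == 0:
        raise ValueError("no PSP durations below the cutoff: summary undefined")
    return {
        "mean_ms": float(kept.mean()),
        "median_ms": float(np.median(kept)),
        "n": int(kept.size),
        "n_excluded": int(durs.size - kept.size),
    }
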