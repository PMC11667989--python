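"""Domain types and file I/O for motif-aligned intracellular recordings.

A *trial* is one rendition of the song motif: a uniformly sampled
membrane-potential trace (mV) together with the motif onset/offset within
the trace and per-neuron metadata (age group, projection class).  A neuron
is stored on disk as a directory of per-trial trace files sharing one
metadata document.

Times are seconds in files and in `TrialRecording`; analysis outputs use
milliseconds and Hz (the units the field reports in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AGE_GROUPS",
    "PROJECTION_CLASSES",
    "AnalysisParams",
    "FormatError",
    "MotifTime",
    "TrialRecording",
    "ValidationError",
    "read_neuron_dir",
    "read_trial",
    "to_motif_time",
    "write_neuron_dir",
    "write_trial",
]

AGE_GROUPS = ("juvenile", "adult")
PROJECTION_CLASSES = ("HVC_RA", "HVC_X", "unknown")

#: Relative tolerance for the uniform-sampling check in :func:`read_trial`.
SAMPLING_UNIFORMITY_PPM = 1e-6


class ValidationError(ValueError):
    """A recording or parameter set violates a domain invariant."""


class FormatError(ValueError):
    """A file on disk does not conform to the expected text format."""


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the detection and statistics pipeline.

    Defaults follow the analysis conventions of sharp-electrode HVC
    recordings: spikes exceed the trace mean by 15 mV, a burst requires
    adjacent-spike rates strictly above 100 Hz on one depolarization event,
    burst identities recur within +/-20 ms across renditions, PSPs exceed
    2 mV trough-to-peak and durations >=35 ms are discarded as unreliable.

    Attributes
    ----------
    spike_threshold:
        mV above the whole-trial mean voltage a spike peak must exceed.
    burst_rate_min:
        Hz; adjacent spikes join a burst only if their instantaneous rate
        strictly exceeds this (100 Hz => ISI < 10 ms).
    recur_window:
        ms; two-sided window for chaining burst onsets across consecutive
        trials.
    preburst_window:
        ms of subthreshold voltage analyzed before each burst onset.
    psp_min_amplitude:
        mV; PSP events must strictly exceed this trough-to-peak amplitude.
    psp_max_duration:
        ms; PSP durations at or above this are excluded from duration
        summaries.
    progression_max_spikes:
        bursts with more spikes than this are excluded from the firing-rate
        progression analysis.
    min_spike_height / max_resting_potential:
        recording-quality gates (mV): spikes must reach at least 30 mV and
        the resting potential must sit below -50 mV.
    depolarization_floor:
        mV above the trace mean the inter-spike subthreshold voltage must
        stay for two spikes to count as riding the same depolarization
        event.
    spike_cut_pre / spike_cut_post:
        ms excised around each spike peak before subthreshold analysis.
    psp_lowpass_hz:
        cutoff of the low-pass filter used for PSP peak candidacy only.
    """

    spike_threshold: float = 15.0
    burst_rate_min: float = 100.0
    recur_window: float = 20.0
    preburst_window: float = 15.0
    psp_min_amplitude: float = 2.0
    psp_max_duration: float = 35.0
    progression_max_spikes: int = 6
    min_spike_height: float = 30.0
    max_resting_potential: float = -50.0
    depolarization_floor: float = 5.0
    spike_cut_pre: float = 2.0
    spike_cut_post: float = 5.0
    psp_lowpass_hz: float = 200.0

    def __post_init__(self) -> None:
        positive = (
            "spike_threshold", "burst_rate_min", "recur_window",
            "preburst_window", "psp_min_amplitude", "psp_max_duration",
            "progression_max_spikes", "min_spike_height",
            "depolarization_floor", "spike_cut_pre", "spike_cut_post",
            "psp_lowpass_hz",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_resting_potential >= 0:
            raise ValidationError("max_resting_potential must be negative")


@dataclass(frozen=True)
class TrialRecording:
    """One motif rendition: voltage trace plus alignment and metadata."""

    neuron_id: str
    trial_index: int
    sampling_rate: float
    voltage: np.ndarray
    motif_onset: float
    motif_offset: float
    age_group: str
    projection_class: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        object.__setattr__(self, "voltage", v)
        if self.trial_index < 0:
            raise ValidationError("trial_index must be >= 0")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if v.ndim != 1 or v.size == 0:
            raise ValidationError("voltage must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValidationError("voltage contains non-finite samples")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"age_group must be one of {AGE_GROUPS}")
        if self.projection_class not in PROJECTION_CLASSES:
            raise ValidationError(
                f"projection_class must be one of {PROJECTION_CLASSES}"
            )
        if not (0 <= self.motif_onset < self.motif_offset <= self.duration):
            raise ValidationError(
                "motif window must satisfy 0 <= onset < offset <= duration "
                f"(got {self.motif_onset}-{self.motif_offset} in "
                f"{self.duration:.4f} s)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.voltage.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.voltage.size / self.sampling_rate

    @property
    def motif_duration_ms(self) -> float:
        return (self.motif_offset - self.motif_onset) * 1000.0

    def times(self) -> np.ndarray:
        """Sample times in seconds (0 at the first sample)."""
        return np.arange(self.voltage.size) / self.sampling_rate

    def motif_slice(self) -> slice:
        """Index slice covering the motif window (inclusive of both edges)."""
        i0 = int(round(self.motif_onset * self.sampling_rate))
        i1 = int(round(self.motif_offset * self.sampling_rate))
        return slice(i0, min(i1 + 1, self.voltage.size))

    def in_motif(self, t: float) -> bool:
        return self.motif_onset <= t <= self.motif_offset

    def with_voltage(self, voltage: np.ndarray) -> "TrialRecording":
        return replace(self, voltage=voltage)


@dataclass(frozen=True)
class MotifTime:
    """One event time expressed on all three motif-aligned scales."""

    absolute: float        # seconds from trace start
    relative_ms: float     # ms from motif onset
    percent: float         # 0-100 of motif duration

    @property
    def in_motif(self) -> bool:
        return 0.0 <= self.percent <= 100.0


def to_motif_time(t: float, trial: TrialRecording) -> MotifTime:
    """Express an absolute time as motif-relative ms and percent.

    Events before motif onset carry negative ``relative_ms``/``percent``
    and are flagged out-of-motif via :attr:`MotifTime.in_motif`.
    """
    rel_ms = (t - trial.motif_onset) * 1000.0
    pct = 100.0 * rel_ms / trial.motif_duration_ms
    return MotifTime(absolute=t, relative_ms=rel_ms, percent=pct)


# ---------------------------------------------------------------------------
# File I/O: plain delimited text traces + JSON metadata sidecars.
# ---------------------------------------------------------------------------

TRACE_HEADER = "time_s,voltage_mV"


def write_trial(trial: TrialRecording, trace_file: Path | str,
                meta_file: Path | str | None = None) -> None:
    """Write a trial as a two-column CSV, updating the JSON metadata sidecar.

    The sidecar is shared by all trials of a neuron; the trial's entry is
    keyed by the trace file name.
    """
    trace_file = Path(trace_file)
    t = trial.times()
    with open(trace_file, "w") as fh:
        fh.write(TRACE_HEADER + "\n")
        for ti, vi in zip(t, trial.voltage):
            fh.write(f"{ti:.7f},{vi:.6f}\n")
    if meta_file is None:
        return
    meta_file = Path(meta_file)
    doc: dict = {"neuron_id": trial.neuron_id,
                 "age_group": trial.age_group,
                 "projection_class": trial.projection_class,
                 "trials": {}}
    if meta_file.exists():
        doc = json.loads(meta_file.read_text())
    doc.setdefault("trials", {})
    doc["neuron_id"] = trial.neuron_id
    doc["age_group"] = trial.age_group
    doc["projection_class"] = trial.projection_class
    doc["trials"][trace_file.name] = {
        "trial_index": trial.trial_index,
        "motif_onset_s": trial.motif_onset,
        "motif_offset_s": trial.motif_offset,
    }
    meta_file.write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_trial(trace_file: Path | str, meta_file: Path | str) -> TrialRecording:
    """Read one trial from a two-column CSV plus its metadata sidecar.

    The sampling rate is inferred from the median time step and checked
    uniform to 1 ppm; non-uniform sampling raises :class:`FormatError`.
    """
    trace_file = Path(trace_file)
    meta_file = Path(meta_file)
    try:
        data = np.loadtxt(trace_file, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse {trace_file}: {exc}") from exc
    if data.shape[1] != 2 or data.shape[0] < 2:
        raise FormatError(
            f"{trace_file}: expected >=2 rows of time_s,voltage_mV"
        )
    t, v = data[:, 0], data[:, 1]
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0:
        raise FormatError(f"{trace_file}: non-increasing time column")
    if np.any(np.abs(steps - dt) > SAMPLING_UNIFORMITY_PPM * dt + 1e-12):
        raise FormatError(f"{trace_file}: sampling is not uniform to 1 ppm")
    if np.any(~np.isfinite(v)):
        raise ValidationError(f"{trace_file}: NaN/inf voltage sample")
    doc = json.loads(meta_file.read_text())
    entry = doc.get("trials", {}).get(trace_file.name)
    if entry is None:
        raise FormatError(
            f"{meta_file} has no entry for trace {trace_file.name!r}"
        )
    return TrialRecording(
        neuron_id=doc["neuron_id"],
        trial_index=int(entry["trial_index"]),
        sampling_rate=1.0 / dt,
        voltage=v,
        motif_onset=float(entry["motif_onset_s"]),
        motif_offset=float(entry["motif_offset_s"]),
        age_group=doc["age_group"],
        projection_class=doc.get("projection_class", "unknown"),
    )


def write_neuron_dir(trials: Sequence[TrialRecording], out_dir: Path | str) -> Path:
    """Write a neuron's trials as ``trial_XXX.csv`` files + ``metadata.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = out_dir / "metadata.json"
    for trial in trials:
        write_trial(trial, out_dir / f"trial_{trial.trial_index:03d}.csv", meta)
    return out_dir


def read_neuron_dir(neuron_dir: Path | str) -> list[TrialRecording]:
    """Read all trials of one neuron directory, sorted by trial index."""
    neuron_dir = Path(neuron_dir)
    meta = neuron_dir / "metadata.json"
    if not meta.exists():
        raise FormatError(f"{neuron_dir}: missing metadata.json")
    names = json.loads(meta.read_text()).get("trials", {})
    trials = [read_trial(neuron_dir / name, meta) for name in sorted(names)]
    trials.sort(key=lambda tr: tr.trial_index)
    rates = {tr.sampling_rate for tr in trials}
    if len(trials) and (max(rates) - min(rates)) > SAMPLING_UNIFORMITY_PPM * max(rates):
        raise ValidationError(f"{neuron_dir}: sampling rate differs across trials")
    return trials
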