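"""Synthetic motif-aligned membrane-potential trials with ground truth.

The simulator emulates sharp-electrode recordings of HVC projection
neurons during singing: a hyperpolarized resting potential, sparse
motif-locked bursts (0-4 identities per neuron) riding slow
depolarization envelopes, extra single spikes, a train of depolarizing
PSP kernels (difference of exponentials), and additive Gaussian noise.
Juvenile and adult presets encode the two age groups' firing and
synaptic statistics: intra-burst rates near 226 vs 388 Hz, PSP rates
near 12.8 vs 16.1 Hz, PSP amplitudes near 6.1 vs 5.5 mV, PSP durations
near 21 vs 18 ms, burst reliabilities near 0.60 vs 0.86, and more
single spikes in juveniles.

Every injected event is recorded in a :class:`GroundTruth`, so detector
sensitivity and parameter recovery can be measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache
from pathlib import Path
import numpy as np

from .trace_model import (AnalysisParams, TrialRecording, write_neuron_dir)

__all__ = [
    "GroundTruth",
    "NeuronTemplate",
    "TrialTruth",
    "make_preset",
    "simulate_cohort",
    "simulate_trial",
    "solve_psp_taus",
]

#: Trace padding around the motif window, seconds.
PRE_PAD_S = 0.15
POST_PAD_S = 0.10

#: Depolarization envelope under bursts / single spikes, mV and ms.
BURST_ENVELOPE_MV = 10.0
SINGLE_ENVELOPE_MV = 4.0
ENVELOPE_RISE_MS = 15.0
ENVELOPE_FALL_MS = 15.0

#: Gaussian spike waveform width (standard deviation), ms.
SPIKE_SD_MS = 0.18

#: Minimum separation enforced between PSP events and around spikes, s.
PSP_DEAD_TIME_S = 0.015
PSP_SPIKE_CLEARANCE_S = 0.015

#: Minimum spacing of single spikes from any other spike, s.
SINGLE_CLEARANCE_S = 0.020

# Age-group preset conditions (study statistics the simulator emulates).
PRESET_CONDITIONS = {
    "juvenile": dict(
        intra_burst_rate_mean=226.09, intra_burst_rate_sd=20.0,
        intra_burst_rate_range=(180.0, 280.0),
        burst_reliability_mean=0.60, burst_reliability_sd=0.04,
        burst_reliability_range=(0.45, 0.75),
        identity_probs=(0.05, 0.20, 0.40, 0.25, 0.10),   # counts 0..4
        single_spike_rate=1.5,
        psp_rate_mean=12.82, psp_rate_sd=1.0,
        psp_amplitude_mean=6.10, psp_amplitude_sd=1.0,
        psp_duration_target_ms=21.04,
        resting_potential=-62.0,
        spike_height=48.0,
        burst_jitter_sd_ms=3.0,
    ),
    "adult": dict(
        intra_burst_rate_mean=387.68, intra_burst_rate_sd=35.0,
        intra_burst_rate_range=(300.0, 480.0),
        burst_reliability_mean=0.86, burst_reliability_sd=0.03,
        burst_reliability_range=(0.80, 0.95),
        identity_probs=(0.10, 0.55, 0.20, 0.10, 0.05),
        single_spike_rate=0.5,
        psp_rate_mean=16.12, psp_rate_sd=1.0,
        psp_amplitude_mean=5.49, psp_amplitude_sd=1.0,
        psp_duration_target_ms=17.79,
        resting_potential=-68.0,
        spike_height=52.0,
        burst_jitter_sd_ms=2.0,
    ),
}

#: Spikes-per-burst distribution over counts 2..6 (median 3 in both groups).
SPIKES_PER_BURST_PROBS = (0.20, 0.35, 0.25, 0.15, 0.05)


@dataclass(frozen=True)
class NeuronTemplate:
    """Generative parameters of one synthetic neuron."""

    age_group: str
    n_burst_identities: int
    burst_times_percent: tuple
    burst_jitter_sd: float          # ms
    burst_reliability: float
    spikes_per_burst_probs: tuple   # over counts 2..6
    intra_burst_rate: float         # Hz
    single_spike_rate: float        # events per motif
    psp_rate: float                 # Hz
    psp_amplitude_mean: float       # mV
    psp_amplitude_sd: float         # mV
    psp_tau_rise: float             # ms
    psp_tau_decay: float            # ms
    psp_duration_target: float      # ms (what the detector should measure)
    psp_locking: float = 0.9        # fraction of PSP rate that is motif-locked
    spike_height: float = 48.0      # mV
    resting_potential: float = -65.0  # mV
    noise_sd: float = 1.0           # mV
    motif_duration: float = 600.0   # ms
    sampling_rate: float = 20_000.0  # Hz

    def __post_init__(self) -> None:
        if not 0 <= self.n_burst_identities <= 4:
            raise ValueError("n_burst_identities must be 0..4")
        if len(self.burst_times_percent) != self.n_burst_identities:
            raise ValueError("burst_times_percent length mismatch")
        if not 0.0 <= self.burst_reliability <= 1.0:
            raise ValueError("burst_reliability must be in [0, 1]")
        if not self.intra_burst_rate > 100.0:
            raise ValueError("intra_burst_rate must exceed 100 Hz")
        if self.spike_height < 30.0:
            raise ValueError("spike_height below the 30 mV quality gate")
        if self.resting_potential >= -50.0:
            raise ValueError("resting potential must sit below -50 mV")


@dataclass(frozen=True)
class TrialTruth:
    """Injected events of one trial (times in seconds from trace start)."""

    spike_times: tuple
    burst_labels: tuple          # identity index per spike, None for singles
    psp_peak_times: tuple
    psp_amplitudes: tuple
    psp_durations_ms: tuple

    @property
    def single_spike_times(self) -> tuple:
        return tuple(t for t, l in zip(self.spike_times, self.burst_labels)
                     if l is None)

    @property
    def burst_spike_times(self) -> tuple:
        return tuple(t for t, l in zip(self.spike_times, self.burst_labels)
                     if l is not None)


@dataclass(frozen=True)
class GroundTruth:
    """Per-trial truths for one neuron."""

    neuron_id: str
    trials: tuple                # TrialTruth per trial, ordered by index


# ---------------------------------------------------------------------------
# PSP kernel and its numerical calibration
# ---------------------------------------------------------------------------

def psp_kernel(t_s: np.ndarray, amplitude: float, tau_rise_ms: float,
               tau_decay_ms: float) -> np.ndarray:
    """Difference-of-exponentials PSP, normalized to peak ``amplitude``."""
    tr = tau_rise_ms / 1000.0
    td = tau_decay_ms / 1000.0
    raw = np.exp(-t_s / td) - np.exp(-t_s / tr)
    t_peak = (tr * td / (td - tr)) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    out = amplitude * raw / peak
    out[t_s < 0] = 0.0
    return out


#: Fixed tau_decay / tau_rise ratio used when solving kinetics.
_TAU_RATIO = 5.0


@lru_cache(maxsize=32)
def solve_psp_taus(target_duration_ms: float, amplitude: float,
                   sampling_rate: float = 20_000.0, noise_sd: float = 1.0,
                   lowpass_hz: float = 200.0) -> tuple[float, float]:
    """Solve PSP time constants so the detector measures a target duration.

    The detector defines duration from the onset trough to the return to
    onset level (or next trough); kinetics therefore cannot be read off
    the target directly.  This calibration simulates isolated kernels of
    the given amplitude on a noisy baseline (fixed internal seed), runs
    the PSP detector, and bisects the rise time (decay fixed at 5x rise)
    until the median detected duration matches the target.
    """
    from .subthreshold import SubthresholdTrace, detect_psps
    from .trace_model import AnalysisParams

    params = AnalysisParams(psp_lowpass_hz=lowpass_hz,
                            psp_max_duration=1e9)  # no cutoff while calibrating
    fs = sampling_rate
    spacing_s = 0.150
    n_kernels = 20
    n = int(fs * spacing_s * (n_kernels + 1))
    rng = np.random.default_rng(123_456_789)
    noise = rng.normal(0.0, noise_sd, n)
    onsets = (np.arange(1, n_kernels + 1) * spacing_s * fs).astype(int)
    tail = np.arange(int(0.120 * fs)) / fs

    def measured(tau_r: float) -> float:
        v = noise.copy()
        k = psp_kernel(tail, amplitude, tau_r, _TAU_RATIO * tau_r)
        for i0 in onsets:
            v[i0:i0 + k.size] += k[:max(0, n - i0)]
        trace = SubthresholdTrace(voltage=v, sampling_rate=fs)
        # dummy trial only needed for the signature of detect_psps
        events = detect_psps(trace, None, params)
        durs = [e.duration_ms for e in events
                if any(abs(e.peak_time * fs - i0) < 0.05 * fs for i0 in onsets)]
        return float(np.median(durs)) if durs else 0.0

    # duration grows with tau only while the decay tail still outruns the
    # smoothed noise; beyond ~tau_rise 2.5 ms noise troughs truncate the
    # event and the mapping folds back, so bisection stays below that
    lo, hi = 0.3, 2.5
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if measured(mid) < target_duration_ms:
            lo = mid
        else:
            hi = mid
    tau_r = 0.5 * (lo + hi)
    return float(tau_r), float(_TAU_RATIO * tau_r)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float = np.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def make_preset(age_group: str, seed: int,
                noise_sd: float = 1.0, motif_duration: float = 600.0,
                sampling_rate: float = 20_000.0) -> NeuronTemplate:
    """Draw a neuron template from the juvenile or adult preset.

    The same (age_group, seed) always yields the identical template.
    """
    if age_group not in PRESET_CONDITIONS:
        raise ValueError(f"unknown age_group {age_group!r}")
    cond = PRESET_CONDITIONS[age_group]
    rng = np.random.default_rng([int(seed), 0xC0FFEE])
    n_ids = int(rng.choice(5, p=cond["identity_probs"]))
    # well-separated in-motif positions so identities stay resolvable
    positions = []
    while len(positions) < n_ids:
        cand = float(rng.uniform(8.0, 85.0))
        if all(abs(cand - p) > 12.0 for p in positions):
            positions.append(cand)
    rate = _truncated_normal(rng, cond["intra_burst_rate_mean"],
                             cond["intra_burst_rate_sd"],
                             *cond["intra_burst_rate_range"])
    rel = _truncated_normal(rng, cond["burst_reliability_mean"],
                            cond["burst_reliability_sd"],
                            *cond["burst_reliability_range"])
    psp_rate = _truncated_normal(rng, cond["psp_rate_mean"],
                                 cond["psp_rate_sd"], 5.0, 30.0)
    amp = _truncated_normal(rng, cond["psp_amplitude_mean"], 0.4, 4.5, 8.0)
    tau_r, tau_d = solve_psp_taus(cond["psp_duration_target_ms"],
                                  cond["psp_amplitude_mean"],
                                  sampling_rate, noise_sd)
    return NeuronTemplate(
        age_group=age_group,
        n_burst_identities=n_ids,
        burst_times_percent=tuple(sorted(positions)),
        burst_jitter_sd=cond["burst_jitter_sd_ms"],
        burst_reliability=rel,
        spikes_per_burst_probs=SPIKES_PER_BURST_PROBS,
        intra_burst_rate=rate,
        single_spike_rate=cond["single_spike_rate"],
        psp_rate=psp_rate,
        psp_amplitude_mean=amp,
        psp_amplitude_sd=cond["psp_amplitude_sd"],
        psp_tau_rise=tau_r,
        psp_tau_decay=tau_d,
        psp_duration_target=cond["psp_duration_target_ms"],
        spike_height=cond["spike_height"],
        resting_potential=cond["resting_potential"],
        noise_sd=noise_sd,
        motif_duration=motif_duration,
        sampling_rate=sampling_rate,
    )


def _envelope_bump(env: np.ndarray, fs: float, t0: float, t1: float,
                   amp: float) -> None:
    """Add a plateau with raised-cosine rise/fall onto ``env`` in place."""
    rise = int(round(ENVELOPE_RISE_MS / 1000.0 * fs))
    fall = int(round(ENVELOPE_FALL_MS / 1000.0 * fs))
    i0 = int(round(t0 * fs))
    i1 = int(round(t1 * fs))
    n = env.size
    a0 = max(0, i0 - rise)
    ramp_up = 0.5 * (1 - np.cos(np.pi * np.arange(i0 - a0) / rise))
    env[a0:i0] = np.maximum(env[a0:i0], amp * ramp_up)
    env[max(0, i0):min(n, i1 + 1)] = np.maximum(
        env[max(0, i0):min(n, i1 + 1)], amp)
    b1 = min(n, i1 + 1 + fall)
    ramp_dn = 0.5 * (1 + np.cos(np.pi * np.arange(b1 - i1 - 1) / fall))
    env[i1 + 1:b1] = np.maximum(env[i1 + 1:b1], amp * ramp_dn)


def simulate_trial(template: NeuronTemplate, trial_index: int, seed: int,
                   neuron_id: str = "sim",
                   projection_class: str = "HVC_RA",
                   ) -> tuple[TrialRecording, TrialTruth]:
    """Simulate one motif rendition of a neuron.

    The voltage is resting potential + slow drift + burst/single
    depolarization envelopes + stereotyped spike waveforms + PSP kernels
    + Gaussian noise.  Identical (template, trial_index, seed) yields a
    bit-identical trace.  Spike truth times are sample-aligned so that,
    at zero noise, detected peaks equal truth exactly.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(trial_index)])
    fs = template.sampling_rate
    motif_s = template.motif_duration / 1000.0
    motif_onset = PRE_PAD_S
    motif_offset = PRE_PAD_S + motif_s
    n = int(round((PRE_PAD_S + motif_s + POST_PAD_S) * fs))

    def snap(t: float) -> float:
        return round(t * fs) / fs

    # --- spikes -----------------------------------------------------------
    spike_times: list[float] = []
    labels: list[int | None] = []
    spike_counts = np.arange(2, 7)
    for ident, pct in enumerate(template.burst_times_percent):
        if rng.random() >= template.burst_reliability:
            continue
        onset = motif_onset + pct / 100.0 * motif_s \
            + rng.normal(0.0, template.burst_jitter_sd) / 1000.0
        n_sp = int(rng.choice(spike_counts, p=template.spikes_per_burst_probs))
        isis = (1.0 / template.intra_burst_rate) \
            * (1.0 + 0.1 * rng.standard_normal(n_sp - 1))
        # keep ISIs inside the burst regime: above refractory, below 10 ms
        isis = np.clip(isis, 1.5e-3, 9.5e-3)
        times = onset + np.r_[0.0, np.cumsum(isis)]
        times = np.clip(times, motif_onset, motif_offset - 1e-3)
        for t in times:
            spike_times.append(snap(float(t)))
            labels.append(ident)
    # single spikes: Poisson count, rejection-spaced from existing spikes
    n_single = rng.poisson(template.single_spike_rate)
    placed = 0
    for _ in range(200):
        if placed >= n_single:
            break
        cand = snap(float(rng.uniform(motif_onset + 0.005,
                                      motif_offset - 0.005)))
        if all(abs(cand - t) > SINGLE_CLEARANCE_S for t in spike_times):
            spike_times.append(cand)
            labels.append(None)
            placed += 1
    order = np.argsort(spike_times)
    spike_times = [spike_times[i] for i in order]
    labels = [labels[i] for i in order]

    # --- subthreshold scaffold -------------------------------------------
    t_axis = np.arange(n) / fs
    drift = 0.3 * np.sin(2 * np.pi * 0.8 * t_axis + rng.uniform(0, 2 * np.pi))
    v = template.resting_potential + drift

    env = np.zeros(n)
    by_ident: dict[int, list[float]] = {}
    for t, l in zip(spike_times, labels):
        if l is None:
            _envelope_bump(env, fs, t, t, SINGLE_ENVELOPE_MV)
        else:
            by_ident.setdefault(l, []).append(t)
    for times in by_ident.values():
        _envelope_bump(env, fs, min(times), max(times) + 0.002,
                       BURST_ENVELOPE_MV)
    v += env

    # --- PSP train --------------------------------------------------------
    # A motif-locked pattern (same for every trial of a neuron: seeded by
    # ``seed`` only) carries ``psp_locking`` of the event rate; the rest
    # are per-trial events.  Events landing within the spike clearance of
    # this trial's spikes are dropped (the detector discards events at
    # spike-excision windows, so they would have no recoverable truth);
    # the generating rate is inflated by the expected exclusion so the
    # realized event frequency matches the preset.
    psp_times: list[float] = []
    psp_amps: list[float] = []
    if template.psp_rate > 0:
        total_s = n / fs
        # expected exclusion: a zone around each burst identity plus the
        # expected single-spike zones, all of which fall inside the motif;
        # the generating rate is inflated so the realized in-motif
        # frequency matches the preset
        # expected burst span = (E[spikes]-1) ISIs at the template rate,
        # plus the 2 x 15 ms clearance; singles cost one clearance each
        span = 2.5 / template.intra_burst_rate + 2 * PSP_SPIKE_CLEARANCE_S
        zone_s = (template.n_burst_identities * template.burst_reliability
                  * span + template.single_spike_rate
                  * 2 * PSP_SPIKE_CLEARANCE_S)
        avail_motif = max(0.5 * motif_s, motif_s - zone_s)
        lam = template.psp_rate * motif_s / avail_motif
        min_amp = 2.0 * AnalysisParams().psp_min_amplitude

        def _dead_time_rate(rate: float) -> float:
            return rate / max(1e-9, 1.0 - rate * PSP_DEAD_TIME_S)

        def _hardcore(gen: np.random.Generator, rate_eff: float):
            times, amps = [], []
            t_cur = float(gen.exponential(1.0 / rate_eff))
            while t_cur < total_s - 0.02:
                times.append(t_cur)
                amps.append(_truncated_normal(
                    gen, template.psp_amplitude_mean,
                    template.psp_amplitude_sd, min_amp))
                t_cur += PSP_DEAD_TIME_S + float(gen.exponential(1.0 / rate_eff))
            return times, amps

        rng_pattern = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7777])
        # The motif-locked pattern carries a *controlled* number of events
        # (a jittered lattice rather than a Poisson draw): the neuron's PSP
        # rate is a template parameter, and letting the one fixed pattern
        # realization add Poisson count noise would smear it across the
        # cohort.  Irregularity comes from the per-event jitter.
        n_locked = int(round(lam * template.psp_locking * (total_s - 0.04)))
        spacing = (total_s - 0.04) / max(1, n_locked)
        locked_t = np.sort(
            0.02 + (np.arange(n_locked) + 0.5) * spacing
            + rng_pattern.normal(0.0, 0.25 * spacing, n_locked))
        locked_a = [_truncated_normal(rng_pattern,
                                      template.psp_amplitude_mean,
                                      template.psp_amplitude_sd, min_amp)
                    for _ in range(n_locked)]
        free_t, free_a = ([], []) if template.psp_locking >= 1.0 else \
            _hardcore(rng, _dead_time_rate(lam * (1.0 - template.psp_locking)))
        # locked events avoid the template's burst zones by construction
        # of the drop step below; per-trial jitter and gain keep renditions
        # realistic without destroying stereotypy
        for t0, a0 in zip(locked_t, locked_a):
            # small per-trial jitter/gain: renditions differ realistically
            # without washing out the motif-locked structure (kernel rise
            # times are ~1 ms, so timing jitter must stay well below that)
            t_j = t0 + float(rng.normal(0.0, 0.0003))
            a_j = a0 * float(np.clip(rng.normal(1.0, 0.05), 0.7, 1.3))
            if 0.0 < t_j < total_s - 0.02 and a_j > min_amp * 0.9:
                psp_times.append(t_j)
                psp_amps.append(a_j)
        psp_times.extend(free_t)
        psp_amps.extend(free_a)
        keep = [i for i, t0 in enumerate(psp_times)
                if all(abs(t0 - s) > PSP_SPIKE_CLEARANCE_S
                       for s in spike_times)]
        psp_times = [psp_times[i] for i in keep]
        psp_amps = [psp_amps[i] for i in keep]
        order_p = np.argsort(psp_times)
        psp_times = [psp_times[i] for i in order_p]
        psp_amps = [psp_amps[i] for i in order_p]
    tail = np.arange(int(0.120 * fs)) / fs
    t_peak_s = (template.psp_tau_rise * template.psp_tau_decay
                / (template.psp_tau_decay - template.psp_tau_rise)
                * np.log(template.psp_tau_decay / template.psp_tau_rise)) / 1000.0
    for t0, amp in zip(psp_times, psp_amps):
        i0 = int(round(t0 * fs))
        k = psp_kernel(tail, amp, template.psp_tau_rise, template.psp_tau_decay)
        seg = k[:max(0, n - i0)]
        v[i0:i0 + seg.size] += seg

    # --- spike waveforms and noise ---------------------------------------
    half = int(round(5 * SPIKE_SD_MS / 1000.0 * fs))
    wave_t = np.arange(-half, half + 1) / fs
    wave = np.exp(-0.5 * (wave_t / (SPIKE_SD_MS / 1000.0)) ** 2)
    for t in spike_times:
        i = int(round(t * fs))
        lo, hi = max(0, i - half), min(n, i + half + 1)
        v[lo:hi] += template.spike_height * wave[lo - (i - half):hi - (i - half)]
    if template.noise_sd > 0:
        v += rng.normal(0.0, template.noise_sd, n)

    trial = TrialRecording(
        neuron_id=neuron_id, trial_index=trial_index, sampling_rate=fs,
        voltage=v, motif_onset=motif_onset, motif_offset=motif_offset,
        age_group=template.age_group, projection_class=projection_class,
    )
    truth = TrialTruth(
        spike_times=tuple(spike_times),
        burst_labels=tuple(labels),
        psp_peak_times=tuple(t + t_peak_s for t in psp_times),
        psp_amplitudes=tuple(psp_amps),
        psp_durations_ms=tuple(template.psp_duration_target
                               for _ in psp_times),
    )
    return trial, truth


def simulate_cohort(n_neurons: int, age_group: str, trials_per_neuron: int,
                    seed: int, out_dir: Path | str | None = None,
                    noise_sd: float = 1.0, motif_duration: float = 600.0,
                    sampling_rate: float = 20_000.0,
                    ) -> tuple[list[list[TrialRecording]], list[GroundTruth]]:
    """Simulate a cohort of neurons; optionally write it to disk.

    Each neuron gets an independent seeded template and at least 4 trials
    (motif renditions).  With ``out_dir`` set, each neuron is written as a
    directory of trace CSVs + metadata.json + truth.json.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if trials_per_neuron < 4:
        raise ValueError("need >= 4 motif renditions per neuron")
    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s) % (2 ** 31) for s in
                   ss.generate_state(n_neurons, dtype=np.uint64)]
    cohort: list[list[TrialRecording]] = []
    truths: list[GroundTruth] = []
    for i, nseed in enumerate(child_seeds):
        template = make_preset(age_group, nseed, noise_sd=noise_sd,
                               motif_duration=motif_duration,
                               sampling_rate=sampling_rate)
        nid = f"{age_group}_{i:03d}"
        trials, trial_truths = [], []
        for k in range(trials_per_neuron):
            trial, truth = simulate_trial(template, k, nseed, neuron_id=nid)
            trials.append(trial)
            trial_truths.append(truth)
        cohort.append(trials)
        truths.append(GroundTruth(neuron_id=nid, trials=tuple(trial_truths)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        for trials, truth in zip(cohort, truths):
            ndir = write_neuron_dir(trials, out_dir / truth.neuron_id)
            (ndir / "truth.json").write_text(json.dumps({
                "neuron_id": truth.neuron_id,
                "trials": [asdict(t) for t in truth.trials],
            }, indent=1))
    return cohort, truths
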