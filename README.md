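# hvcephys

Analysis of sharp-electrode intracellular recordings from HVC projection
neurons of zebra finches during singing, for electrophysiologists
comparing juvenile (plastic-song) and adult (crystallized-song) birds.
The package covers the full single-cell pipeline — spike, burst and
postsynaptic-potential (PSP) event detection on motif-aligned
membrane-potential traces, burst stereotypy across song renditions,
subthreshold stereotypy, and the juvenile-vs-adult statistical battery —
together with a ground-truthed synthetic simulator of both age groups, so
every stage can be validated without access to raw recordings.

## The measurements

All event detection operates on a voltage trace V(t) (mV, uniformly
sampled) with the song motif window given per trial.

- **Spikes** are peaks of excursions above `mean(V) + 15 mV`, one per
  contiguous suprathreshold excursion.
- **Bursts** are maximal chains of ≥ 2 consecutive spikes whose
  adjacent-spike rate strictly exceeds 100 Hz (ISI < 10 ms) *and* which
  ride the same membrane depolarization event (the spike-excised voltage
  between the peaks stays ≥ mean + 5 mV).
- A burst identity is **recurring** when its onset (first spike, in
  motif-relative time) reappears within ± 20 ms in the next rendition;
  per identity the spike-count stability is
  `Δ-spikes = mean_k |n_k − mode(n)|`.
- **Instantaneous firing rate** of a burst is `n_ISI / Σ ISI` (Hz), the
  reciprocal mean inter-spike interval; the per-ISI progression uses
  `r_i = 1/ISI_i` for bursts of 2–6 spikes.
- **PSP events** on the spike-excised trace are local peaks whose
  trough-to-peak amplitude strictly exceeds 2 mV; their frequency is
  events per motif duration, and durations ≥ 35 ms are excluded from
  duration summaries.
- **Subthreshold stereotypy** of a neuron is the mean pairwise zero-lag
  normalized cross-correlation of its spike-excised, demeaned motif
  traces; the same correlation over 15 ms pre-burst windows gives the
  pre-burst stereotypy.
- Group comparisons use the Wilcoxon rank-sum test (reported as
  median + raw MAD), the pooled two-sample t-test (mean ± SD), and the
  Fisher exact test (probability-mass two-sided rule) for recurring-burst
  counts.

## Worked example

`examples/` holds one short script per capability. From
`examples/01_simulate_and_detect.py`:

```
template: 3 burst identities, intra-burst rate 248 Hz, PSP rate 11.0 Hz

trial 0: 12 spikes detected (12 injected)
  burst at  14.1% of motif: 5 spikes, 16.3 ms, IFR 246 Hz
  burst at  32.9% of motif: 4 spikes, 12.2 ms, IFR 245 Hz
  3 single spikes (3 injected)
```

A juvenile preset neuron fires sparse motif-locked bursts (here two of
its three identities appeared in this rendition, at 246 and 245 Hz —
near the juvenile ~226 Hz regime and well below the adult ~388 Hz) plus
a few single spikes; every detected event matches an injected
ground-truth event. `examples/04_cohort_comparison.py` runs the full
battery on simulated cohorts and prints the comparison table; the
firing-rate and PSP-frequency contrasts separate the age groups while
spikes-per-burst and Δ-spikes do not, mirroring the expected physiology.

Neurons are stored on disk as a directory of two-column CSV traces
(`time_s,voltage_mV`) plus one JSON metadata sidecar; see
`hvcephys.read_neuron_dir` / `hvcephys.summarize_neuron_dir`. A thin CLI
mirrors the stages: `hvcephys simulate | detect | analyze | compare`.

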