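# Methods

## Scope and data model

The package analyzes motif-aligned intracellular membrane-potential
recordings of HVC projection neurons. One *trial* is one rendition of
the song motif: a uniformly sampled voltage trace (mV), the motif
onset/offset within the trace, and per-neuron metadata (age group
juvenile/adult; projection class HVC-RA / HVC-X / unknown, treated as a
label, not inferred from the physiology). Traces are stored as
two-column CSV with a JSON sidecar per neuron — diffable plain text
rather than a binary container, since no standard format is mandated by
this kind of sharp-electrode data. Files carry seconds; analysis outputs
use milliseconds and Hz. Recording-quality gates (spikes ≥ 30 mV,
resting potential below −50 mV) are carried as parameters
(`AnalysisParams.min_spike_height`, `max_resting_potential`) and honored
by the simulator.

## Event detection

**Spikes.** The threshold is the whole-trial mean voltage + 15 mV,
computed per trace (a cross-trial average would smear spike times).
Each contiguous suprathreshold excursion yields one spike at its
maximum; peaks closer than 1 ms are merged (absolute refractory guard).

**Bursts.** Adjacent spikes chain when (a) their instantaneous rate
strictly exceeds `burst_rate_min` (100 Hz ⇒ ISI < 10 ms; "strictly"
implemented with a 1e−9 relative guard so an exactly-10 ms ISI never
joins), and (b) they ride the same depolarization event. Criterion (b)
is operationalized numerically: the spike-excised voltage between the
two peaks must never fall below the trace mean + `depolarization_floor`
(default 5 mV, configurable). The floor value separates burst
depolarization plateaus from baseline in the simulator; whether the
original analyses applied a numeric criterion or judged depolarization
continuity visually is unknowable from the reported methods, so the
floor is a declared, exposed choice. Maximal chains of ≥ 2 spikes are
bursts; everything else is a single spike; the two outputs always
partition the detected spikes.

**Spike excision.** Samples in [peak − 2 ms, peak + 5 ms] (covering the
afterdepolarization without deleting PSPs) are replaced by linear
interpolation; overlapping windows merge first. Interpolation anchors
are 0.3 ms means of the samples just outside the window — a single
noisy boundary sample would otherwise tilt the bridged segment and
occasionally break the depolarization-floor test between burst spikes.

## Burst statistics across renditions

**Recurring bursts.** Matching is chained across *consecutive* trials:
a burst in trial t+1 joins an identity when its motif-relative onset
lies within ± 20 ms (inclusive) of the identity's trial-t onset. At most
one burst per trial per identity; the nearest onset wins, exact ties go
to the earlier burst. Identities spanning ≥ 2 trials are recurring.
Consequences accepted as faithful to the chained definition: slow onset
drift can carry an identity beyond ± 20 ms of its first-trial onset, and
an identity that skips a rendition is closed (a later reappearance
starts a new identity).

**Δ-spikes.** Per identity, the mode of member spike counts (ties broken
toward the smaller count, for determinism) and the mean absolute
deviation from it.

**Firing rate.** The scalar burst IFR is `n_ISI / Σ ISI` — the literal
definition, equal to the reciprocal mean ISI. The progression analysis
needs a per-interval quantity, so it uses `r_i = 1/ISI_i` averaged
across bursts at each ISI index, restricted to bursts of 2–6 spikes;
relative progression subtracts a reference trajectory. Centering uses
each group's own mean trajectory by default; a cross-group reference can
be passed explicitly (`burst_relative_rates`), since which convention
the field's printed numbers used is ambiguous.

**Pre-burst windows.** The 15 ms of spike-excised, demeaned voltage
before each burst onset; bursts starting < 15 ms into the trace are
skipped with a warning. Pre-burst stereotypy is the mean pairwise
zero-lag correlation of these windows within a neuron.

## Subthreshold analysis

**Stereotypy.** Trials are spike-excised, restricted to the motif
window, demeaned, and correlated pairwise at zero lag (inner product
over the product of norms). Length mismatches (tempo variability) are
resolved by linear resampling onto the shorter trial. Zero-variance
input raises rather than returning 0.

**PSP detection.** Peak *candidacy* runs on a 200 Hz low-passed copy
(4th-order Butterworth, zero-phase), with a 0.5 mV prominence floor so
residual noise ripples on a decay cannot split one event in two.
Amplitude is trough-to-peak — the only baseline-drift-proof local
definition — measured on the *unsmoothed* excised trace as the
difference of ± 0.5 ms windowed means at the smoothed peak and its
preceding local minimum; single-sample differences at 10–40 kHz would
be dominated by sample noise. Events must strictly exceed 2 mV; events
whose peak falls on an excised sample are discarded. Duration runs from
onset until the smoothed trace first returns to the onset level, or to
the next local minimum, whichever is earlier (well-defined on
overlapping events). Durations ≥ 35 ms are excluded from duration
summaries (reported with the excluded count); frequency is in-motif
event count over motif duration.

## Group statistics

Wilcoxon rank-sum (exact null when min(n, m) ≤ 10 and tie-free,
otherwise normal approximation with tie and continuity corrections),
pooled-variance two-sample t-test (Welch optional), and the Fisher exact
test computed by hypergeometric enumeration with the probability-mass
two-sided rule (the most common convention; the doubling rule differs
and is deliberately not used). Summaries follow the test family:
median + raw MAD (no 1.4826 consistency factor — the integer-valued MADs
this literature reports imply the raw definition) for rank tests,
mean ± SD for t-tests. The comparison battery reports unadjusted
p-values and logs the number of tests; burst-level metrics (IFR,
duration, spikes per burst, PSP amplitudes) are compared at the event
level, neuron-level metrics (max bursts, stereotypy, PSP frequency,
mean PSP duration) per neuron, and recurring-burst counts pool across
neurons into one 2×2 Fisher table. A flag restricts the battery to the
HVC-RA subset.

## The synthetic generator

`simulate_trial` composes: resting potential (−62 mV juvenile / −68 mV
adult) + a small 0.8 Hz drift (0.3 mV) + burst depolarization envelopes
(10 mV raised-cosine plateaus, 15 ms rise/fall) + stereotyped Gaussian
spike waveforms (σ = 0.18 ms, height 48/52 mV) + difference-of-
exponentials PSP kernels + white Gaussian noise (1 mV). Trials span the
600 ms motif plus 150/100 ms padding at 20 kHz (both configurable).
Spike truth times are sample-aligned, so at zero noise detection
recovers them exactly.

Preset parameters encode the two age groups: intra-burst rate drawn
near 226 Hz (juvenile) vs 388 Hz (adult), burst reliability near 0.60
vs 0.86, burst identities per neuron with median 2 vs 1 (range 0–4),
single spikes 1.5 vs 0.5 per motif, PSP rate near 12.8 vs 16.1 Hz,
PSP amplitude near 6.1 vs 5.5 mV, PSP duration targets 21.0 vs 17.8 ms.
Within-burst ISIs are 1/rate with 10 % multiplicative jitter, clipped to
(1.5, 9.5) ms so injected bursts stay inside the burst regime; burst
onsets jitter by 3 / 2 ms (juvenile/adult) around their motif-percent
positions, which are drawn well separated (≥ 12 % of the motif) so
identities remain resolvable.

**PSP kinetics are calibrated, not assumed.** Only detected durations
are specified, and the detector's duration depends on noise and
smoothing, so τ_rise (with τ_decay = 5 τ_rise) is solved by bisection
until the detector's median measured duration on a fixed-seed
calibration trace of isolated kernels matches the target. The
bisection bracket stays in τ_rise ∈ [0.3, 2.5] ms, where the
duration–τ mapping is monotone (beyond it, smoothed-noise troughs
truncate the slow tails and the mapping folds back).

**PSP train structure.** A fraction `psp_locking` (default 0.9) of the
PSP rate is a motif-locked pattern fixed per neuron, replayed every
rendition with 0.3 ms timing jitter and 5 % gain jitter; the remainder
is drawn fresh per trial. The locked pattern is a jittered lattice with
a *controlled* event count rather than a Poisson draw: the pattern is
one realization reused across all trials, and Poisson count noise in
that single realization would add ~√N between-neuron spread to the PSP
frequency, swamping the preset rate parameter it is meant to express.
Event times keep a 15 ms dead time from each other and from spikes
(an event under a spike-excision window has no recoverable truth), and
the generating rate is inflated by the expected in-motif exclusion so
the realized in-motif frequency matches the preset. Amplitudes are
normal, truncated below at 4 mV (2× the detection threshold), so
recovery is well-posed.

**What the generator does not emulate.** Tempo variability (motif
duration is constant), biophysical conductances, inhibitory potentials,
and the absolute level of subthreshold stereotypy: with default locking
and reliability, simulated stereotypy sits near 0.5 — the full-band
1 mV noise and envelope dropout weigh more heavily here than in real
recordings, where measured stereotypy is ~0.8. Fully locked,
fully reliable templates do reach the ≥ 0.8 regime, which is what the
stereotypy recovery tests exercise. Passing tests therefore validate
the pipeline's operations and their relative group contrasts, not the
absolute stereotypy scale of real data. PSP-rate spread across neurons
is σ = 1 Hz by design: together with estimation noise it keeps the
prescribed cohort calibration (n = 20 per group flags the rate and
frequency contrasts at p < 0.05 in ≥ 95 % of replicates) satisfied with
margin; real cohorts show broader spread (MAD ≈ 3.6–3.9 Hz), which
would roughly halve that power.

## Numerical and size choices

Sampling uniformity on read is checked to 1 ppm against the median time
step. Fisher p-values guard probability ties with a 1e−7 relative
tolerance. Validation sizes: detection recovery uses 100 trials per
preset; parameter recovery uses cohorts of 20 neurons × 4 trials per
age group with 50 replicate cohorts for the power check (the acceptance
script reports 20 replicates). Degenerate inputs signal rather than
default: zero bursts (recurring fraction), zero-variance traces
(correlation), empty duration summaries, and zero pooled variance with
unequal means (t-test) all raise `ValueError`.
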