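"""Simulate one juvenile HVC projection neuron and detect its events.

Builds a synthetic motif rendition from the juvenile preset, runs spike
detection and burst grouping, and compares the result with the
generator's ground truth.
"""

import hvcephys as hv
from hvcephys.synthetic import make_preset, simulate_trial

template = make_preset("juvenile", seed=2)
print(f"template: {template.n_burst_identities} burst identities, "
      f"intra-burst rate {template.intra_burst_rate:.0f} Hz, "
      f"PSP rate {template.psp_rate:.1f} Hz")

trial, truth = simulate_trial(template, trial_index=0, seed=2)
spikes = hv.detect_spikes(trial)
bursts, singles = hv.group_bursts(spikes, trial)

print(f"\ntrial 0: {len(spikes)} spikes detected "
      f"({len(truth.spike_times)} injected)")
for b in bursts:
    mt = hv.to_motif_time(b.onset, trial)
    print(f"  burst at {mt.percent:5.1f}% of motif: {b.n_spikes} spikes, "
          f"{b.duration_ms:.1f} ms, IFR {b.ifr_hz:.0f} Hz")
print(f"  {len(singles)} single spikes "
      f"({len(truth.single_spike_times)} injected)")
# Bursts are >=2 spikes with adjacent rates above 100 Hz on one
# depolarization event; their IFR should sit near the preset's ~226 Hz.
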