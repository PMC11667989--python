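import numpy as np
import pytest

from hvcephys import AnalysisParams, TrialRecording


@pytest.fixture
def params():
    return AnalysisParams()


def build_trial(voltage, fs=20_000.0, motif=(0.05, 0.65), neuron_id="n0",
                trial_index=0, age_group="adult", projection_class="HVC_RA"):
    """Construct a TrialRecording straight from a voltage array."""
    return TrialRecording(
        neuron_id=neuron_id, trial_index=trial_index, sampling_rate=fs,
        voltage=np.asarray(voltage, dtype=float),
        motif_onset=motif[0], motif_offset=motif[1],
        age_group=age_group, projection_class=projection_class,
    )


def spike_train_trace(spike_times_s, fs=20_000.0, duration_s=0.7,
                      baseline=-65.0, spike_height=40.0,
                      envelope=None):
    """Baseline trace with Gaussian spike bumps and an optional envelope.

    ``envelope`` is a list of (t0_s, t1_s, mV) plateaus added beneath the
    spikes, to emulate the membrane depolarization bursts ride on.
    """
    n = int(round(duration_s * fs))
    v = np.full(n, baseline)
    if envelope:
        for t0, t1, amp in envelope:
            v[int(t0 * fs):int(t1 * fs)] += amp
    sd = 0.18e-3
    half = int(round(5 * sd * fs))
    w = np.exp(-0.5 * (np.arange(-half, half + 1) / fs / sd) ** 2)
    for t in spike_times_s:
        i = int(round(t * fs))
        lo, hi = max(0, i - half), min(n, i + half + 1)
        v[lo:hi] += spike_height * w[lo - (i - half):hi - (i - half)]
    return v


@pytest.fixture
def make_trial():
    return build_trial


@pytest.fixture
def make_spike_trace():
    return spike_train_trace
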