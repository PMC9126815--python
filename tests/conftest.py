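import numpy as np
import pytest

from socialphys import ArenaLayout
from socialphys.synth import SyntheticNeuron


@pytest.fixture
def layout() -> ArenaLayout:
    return ArenaLayout()


@pytest.fixture
def neuron() -> SyntheticNeuron:
    """Default MSN-like cell: rheobase between 350 and 400 pA."""
    return SyntheticNeuron()


def lif_closed_form_spike_times(neuron: SyntheticNeuron, i_pa: float,
                                onset: float, duration: float) -> list[float]:
    """Independent closed-form oracle for noiseless LIF spike times.

    First spike at onset + τ·ln((V∞ − v_rest)/(V∞ − v_th)); subsequent
    interspike intervals are refractory + τ·ln((V∞ − v_reset)/(V∞ − v_th)).
    No spikes when V∞ does not exceed threshold.
    """
    v_inf, tau_ms = neuron.steady_state(i_pa)
    tau = tau_ms * 1e-3
    if v_inf <= neuron.v_threshold:
        return []
    times = []
    t = onset + tau * np.log((v_inf - neuron.v_rest) / (v_inf - neuron.v_threshold))
    isi = neuron.refractory * 1e-3 + tau * np.log(
        (v_inf - neuron.v_reset) / (v_inf - neuron.v_threshold))
    while t <= onset + duration:
        times.append(t)
        t += isi
    return times
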