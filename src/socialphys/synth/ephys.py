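"""Synthetic patch-clamp data: leaky integrate-and-fire sweeps, ramp
recordings with a blocker-sensitive conductance, and biexponential EPSCs.

The LIF neuron doubles as an MSN stand-in for the excitability
protocol: with conductances in nS, potentials in mV and currents in pA,
the subthreshold dynamics are

    C dV/dt = −g_L (V − v_rest) − g_t (V − E_t) + I

with C = membrane_tau / R_in and g_L = 1000 / R_in.  A spike is emitted
when V reaches threshold; V then rests at v_reset for the refractory
period.  Noiseless sweeps are integrated event-exactly (exponential
bridge between samples, analytic threshold-crossing time), so spike
counts agree with the closed-form interspike-interval formula to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ephys import RampRecording, SweepSet


@dataclass
class SyntheticNeuron:
    """Leaky integrate-and-fire parameters (MSN-flavoured defaults)."""

    membrane_tau: float = 10.0       # ms
    input_resistance: float = 100.0  # MΩ
    v_rest: float = -80.0            # mV
    v_threshold: float = -45.0       # mV
    v_reset: float = -80.0           # mV
    refractory: float = 2.0          # ms
    trpv4_conductance: float = 0.0   # nS
    trpv4_reversal: float = 0.0      # mV

    def __post_init__(self) -> None:
        if self.v_reset >= self.v_threshold:
            raise ValueError("v_reset must be below v_threshold")
        if self.membrane_tau <= 0 or self.input_resistance <= 0:
            raise ValueError("membrane_tau and input_resistance must be positive")
        if self.trpv4_conductance < 0:
            raise ValueError("conductances must be non-negative")

    @property
    def g_leak(self) -> float:
        """Leak conductance in nS."""
        return 1000.0 / self.input_resistance

    def steady_state(self, i_pa: float) -> tuple[float, float]:
        """(V_inf in mV, effective tau in ms) under constant current."""
        g_tot = self.g_leak + self.trpv4_conductance
        v_inf = (self.g_leak * self.v_rest
                 + self.trpv4_conductance * self.trpv4_reversal + i_pa) / g_tot
        tau_eff = self.membrane_tau * self.g_leak / g_tot
        return v_inf, tau_eff


SPIKE_PEAK_MV = 30.0  # marker value written at the spike sample


def simulate_fi_sweeps(neuron: SyntheticNeuron,
                       steps: np.ndarray | None = None,
                       step_dur: float = 0.5, pre_dur: float = 0.1,
                       post_dur: float = 0.1, rate: float = 20000.0,
                       noise_sd: float = 0.0, seed: int = 0,
                       ) -> tuple[SweepSet, dict[float, np.ndarray]]:
    """Simulate the excitability protocol (current steps of 500 ms).

    Default steps 0..500 pA in 50 pA increments.  Returns the sweep set
    and the true spike times per step (absolute, in seconds).  For
    ``noise_sd = 0`` integration is event-exact; with noise a Gaussian
    voltage perturbation of SD ``noise_sd`` mV is added per sample via
    Euler–Maruyama stepping.
    """
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    if steps is None:
        steps = np.arange(0, 501, 50, dtype=float)
    steps = np.asarray(steps, float)
    if np.any(np.diff(steps) < 0):
        raise ValueError("steps must be sorted ascending")
    rng = np.random.default_rng(seed)
    n = int(round((pre_dur + step_dur + post_dur) * rate))
    t = np.arange(n) / rate
    traces = np.empty((steps.size, n))
    truth: dict[float, np.ndarray] = {}
    for k, i_pa in enumerate(steps):
        inj = np.where((t >= pre_dur) & (t < pre_dur + step_dur), i_pa, 0.0)
        if noise_sd == 0:
            v, spikes = _integrate_exact(neuron, t, inj, rate)
        else:
            v, spikes = _integrate_noisy(neuron, t, inj, rate, noise_sd, rng)
        traces[k] = v
        truth[float(i_pa)] = np.asarray(spikes)
    sweeps = SweepSet(mode="current-clamp", t=t, traces=traces,
                      sweep_labels=steps, rate=rate)
    return sweeps, truth


def _integrate_exact(neuron, t, inj, rate):
    """Event-exact noiseless LIF integration sampled on the grid.

    Between samples the membrane follows the exponential bridge towards
    V_inf; threshold crossings are located analytically, so spike times
    carry no discretization error.  The injected current is held at its
    left-sample value over each inter-sample interval.
    """
    v = np.empty(t.size)
    spikes: list[float] = []
    v_now = neuron.v_rest
    refr_until = -np.inf
    v[0] = v_now
    for i in range(1, t.size):
        t_now, ti = t[i - 1], t[i]
        v_inf, tau = neuron.steady_state(inj[i - 1])
        tau_s = tau * 1e-3
        spiked_here = False
        while t_now < ti:
            if t_now < refr_until:
                t_now = min(refr_until, ti)
                v_now = neuron.v_reset
                continue
            if neuron.v_threshold > v_now and v_inf > neuron.v_threshold:
                t_cross = t_now + tau_s * np.log(
                    (v_inf - v_now) / (v_inf - neuron.v_threshold))
            else:
                t_cross = np.inf
            if t_cross <= ti:
                spikes.append(float(t_cross))
                refr_until = t_cross + neuron.refractory * 1e-3
                t_now = t_cross
                v_now = neuron.v_reset
                spiked_here = True
            else:
                v_now = v_inf + (v_now - v_inf) * np.exp(-(ti - t_now) / tau_s)
                t_now = ti
        if spiked_here:
            v[i] = SPIKE_PEAK_MV  # one marker sample per spike
        elif ti < refr_until:
            v[i] = neuron.v_reset
        else:
            v[i] = v_now
    return v, spikes


def _integrate_noisy(neuron, t, inj, rate, noise_sd, rng):
    dt = 1.0 / rate
    v = np.empty(t.size)
    spikes = []
    v_now = neuron.v_rest
    refr_until = -np.inf
    for i in range(t.size):
        if t[i] < refr_until:
            v_now = neuron.v_reset
            v[i] = v_now
            continue
        v_inf, tau = neuron.steady_state(inj[i])
        decay = np.exp(-dt / (tau * 1e-3))
        v_now = v_inf + (v_now - v_inf) * decay + noise_sd * rng.normal()
        if v_now >= neuron.v_threshold:
            spikes.append(t[i])
            refr_until = t[i] + neuron.refractory * 1e-3
            v[i] = SPIKE_PEAK_MV
            v_now = neuron.v_reset
        else:
            v[i] = v_now
    return v, spikes


def simulate_ramp_session(neuron: SyntheticNeuron,
                          v_start: float = -100.0, v_stop: float = 100.0,
                          n_v: int = 201, period: float = 5.0,
                          baseline_dur: float = 300.0, drug_dur: float = 1200.0,
                          noise_sd: float = 0.0, seed: int = 0) -> RampRecording:
    """Repeated voltage-ramp sweeps with the channel blocked mid-session.

    Each sweep samples I(V) on the −100..+100 mV ramp grid:
    leak g_L·(V − v_rest) plus, during baseline only, the
    blocker-sensitive term g_t·(V − E_t).  The drug removes the Trpv4
    term from ``drug_onset = baseline_dur`` onward.  Noise is additive
    Gaussian per sample in pA.
    """
    if period <= 0 or baseline_dur <= 0 or drug_dur <= 0:
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    v_grid = np.linspace(v_start, v_stop, n_v)
    times = np.arange(0.0, baseline_dur + drug_dur, period)
    leak = neuron.g_leak * (v_grid - neuron.v_rest)
    trpv4 = neuron.trpv4_conductance * (v_grid - neuron.trpv4_reversal)
    currents = np.empty((times.size, n_v))
    for k, ts in enumerate(times):
        i_v = leak + (trpv4 if ts < baseline_dur else 0.0)
        if noise_sd > 0:
            i_v = i_v + rng.normal(0, noise_sd, n_v)
        currents[k] = i_v
    return RampRecording(sweep_times=times, currents=currents,
                         v_grid=v_grid, drug_onset=baseline_dur)


def simulate_epsc_sweeps(holding_levels: list[float],
                         peak_amplitudes: dict[float, list[float]],
                         stim_onsets: list[float],
                         duration: float = 0.2, rate: float = 20000.0,
                         rise_tau: float = 0.001, decay_tau: float = 0.006,
                         nmda_fraction: dict[float, float] | None = None,
                         nmda_decay: float = 0.08, noise_sd: float = 0.0,
                         seed: int = 0) -> SweepSet:
    """Biexponential EPSC sweeps for the synaptic-ratio protocols.

    ``peak_amplitudes[holding]`` lists the fast-component peak (pA,
    signed) per stimulus at that holding potential; an optional
    slow NMDA-like component (fraction of the fast peak, slower decay)
    can be mixed in per holding level.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    traces = []
    for hold in holding_levels:
        trace = np.zeros(n)
        amps = peak_amplitudes[hold]
        frac = (nmda_fraction or {}).get(hold, 0.0)
        for s0, amp in zip(stim_onsets, amps):
            rel = t - s0
            kern = _unit_biexp(rel, rise_tau, decay_tau)
            trace += amp * kern
            if frac:
                trace += amp * frac * _unit_biexp(rel, rise_tau, nmda_decay)
        if noise_sd > 0:
            trace += rng.normal(0, noise_sd, n)
        traces.append(trace)
    return SweepSet(mode="voltage-clamp", t=t, traces=np.vstack(traces),
                    sweep_labels=np.asarray(holding_levels, float), rate=rate,
                    stim_onsets=np.asarray(stim_onsets, float))


def _unit_biexp(rel: np.ndarray, rise: float, decay: float) -> np.ndarray:
    k = np.where(rel >= 0, np.exp(-np.maximum(rel, 0) / decay)
                 - np.exp(-np.maximum(rel, 0) / rise), 0.0)
    tp = rise * decay / (decay - rise) * np.log(decay / rise)
    return k / (np.exp(-tp / decay) - np.exp(-tp / rise))
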