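"""Synthetic two-channel photometry with event-locked GCaMP transients.

Generates the raw interleaved stream the acquisition produces: a single
photodetector sampled at the raw rate while 465 nm and 405 nm LEDs
alternate in a square pulse pattern.  The 465 channel carries slow
photobleaching, event-locked calcium transients (double-exponential
kernel) and noise; the 405 isosbestic channel carries the same bleaching
and any shared motion artifact but no calcium events.
"""

from __future__ import annotations

import numpy as np

from ..photometry import PhotometrySession
from .tracking import SyntheticSessionTruth

RISE_TAU = 0.2  # s, kernel rise; typical for slow GCaMP variants


def transient_kernel(t: np.ndarray, rise_tau: float = RISE_TAU,
                     decay_tau: float = 1.6) -> np.ndarray:
    """Double-exponential calcium transient, normalized to unit peak."""
    if decay_tau <= rise_tau:
        raise ValueError("decay_tau must exceed rise_tau")
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_tau)
                 - np.exp(-np.maximum(t, 0) / rise_tau), 0.0)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return k / peak


def simulate_photometry(truth: SyntheticSessionTruth, duration: float,
                        raw_rate: float = 12000.0, led_alt_rate: float = 40.0,
                        baseline_f: float = 100.0,
                        habituation: tuple[float, float] | None = None,
                        motion_times: list[float] | None = None,
                        motion_amplitude: float = 0.0,
                        motion_duration: float = 0.1,
                        object_amplitude: float | None = None,
                        ) -> PhotometrySession:
    """Simulate a raw interleaved photometry recording.

    The continuous 465 nm signal is

    ``F465(t) = B·exp(−t/bleach_tau)·(1 + Σ_events a·K(t − t_e − latency)) + M(t) + ξ``

    with B the baseline fluorescence, a the event response amplitude in
    ΔF/F units, K the unit-peak double-exponential kernel and M a motion
    artifact shared verbatim with the 405 channel, which otherwise has
    bleaching and noise only.  Social entries from ``truth`` get
    amplitude ``truth.event_response_amplitude``; object entries get
    ``object_amplitude`` (default 0, i.e. no calcium response).

    Each LED alternation period (1/``led_alt_rate``) is split into a
    465 half-pulse then a 405 half-pulse; ``led_state`` labels every raw
    sample.  ``habituation`` defaults to the first half of the session.
    """
    if truth.event_response_amplitude < 0 or truth.noise_sd < 0:
        raise ValueError("amplitude and noise must be non-negative")
    for te in truth.true_entry_times_social + truth.true_entry_times_object:
        if te > duration:
            raise ValueError("duration must cover all entry times")
    rng = np.random.default_rng(truth.seed)
    n = int(round(duration * raw_rate))
    t = np.arange(n) / raw_rate

    bleach = np.exp(-t / truth.bleach_tau) if np.isfinite(truth.bleach_tau) else 1.0
    dff_signal = np.zeros(n)
    obj_amp = 0.0 if object_amplitude is None else object_amplitude
    for times, amp in ((truth.true_entry_times_social,
                        truth.event_response_amplitude),
                       (truth.true_entry_times_object, obj_amp)):
        for te in times:
            if amp > 0:
                onset = te + truth.response_latency
                # kernel support: beyond ~16 decay constants it is < 1e-7
                a = max(int(np.floor(onset * raw_rate)), 0)
                b = min(int(np.ceil((onset + 16 * truth.decay_tau) * raw_rate)) + 1, n)
                dff_signal[a:b] += amp * transient_kernel(
                    t[a:b] - onset, decay_tau=truth.decay_tau)

    motion = np.zeros(n)
    for tm in motion_times or []:
        # shared artifact: half-sine bump added verbatim to both channels
        sel = (t >= tm) & (t < tm + motion_duration)
        motion[sel] += motion_amplitude * np.sin(
            np.pi * (t[sel] - tm) / motion_duration)

    f465 = baseline_f * bleach * (1.0 + dff_signal) + motion
    f405 = baseline_f * bleach + motion
    if truth.noise_sd > 0:
        f465 = f465 + baseline_f * rng.normal(0, truth.noise_sd, n)
        f405 = f405 + baseline_f * rng.normal(0, truth.noise_sd, n)

    # LED alternation: first half-period 465, second half 405
    phase = np.floor(t * led_alt_rate * 2).astype(int) % 2
    led_state = np.where(phase == 0, "465", "405")
    fluor = np.where(phase == 0, f465, f405)

    if habituation is None:
        habituation = (0.0, duration / 2.0)
    return PhotometrySession(t=t, fluor=fluor, led_state=led_state,
                             raw_rate=raw_rate,
                             habituation_interval=habituation,
                             test_interval=(habituation[1], duration))
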