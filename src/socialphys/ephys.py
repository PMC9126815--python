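"""Slice electrophysiology metrics for medium spiny neurons.

Covers the current-clamp excitability protocol (spike counts over
50 pA / 500 ms depolarizing steps from 0 to 500 pA → F–I curve), cell
quality control (resting membrane potential, absence of Ih sag, access
resistance stability), the drug-subtracted ramp I–V curve used to
isolate the Trpv4-mediated current, and voltage-clamp synaptic ratios
(AMPA/NMDA, rectification index, paired-pulse ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SweepSet:
    """A family of sweeps sharing one time base.

    ``traces`` is (n_sweeps, n_samples): membrane potential in mV for
    current clamp, current in pA for voltage clamp.  ``sweep_labels``
    holds the injected current (pA) or holding potential (mV) per sweep.
    """

    mode: str  # 'current-clamp' | 'voltage-clamp'
    t: np.ndarray
    traces: np.ndarray
    sweep_labels: np.ndarray
    rate: float
    stim_onsets: np.ndarray | None = None  # s, for synaptic protocols

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, float))
        if self.traces.shape[1] != len(self.t):
            raise ValueError("traces and time base disagree")
        if len(self.sweep_labels) != self.traces.shape[0]:
            raise ValueError("one label per sweep required")

    def sweep(self, label) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.sweep_labels) == label)
        if idx.size == 0:
            raise KeyError(f"no sweep labelled {label!r}")
        return self.traces[idx[0]]


@dataclass
class FICurve:
    """Spike count per injected current step."""

    steps: np.ndarray  # pA, ascending
    n_ap: np.ndarray   # spikes per step
    cell_id: str = ""
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell": self.cell_id, "step_pA": self.steps,
                             "nAP": self.n_ap, "group": self.group})


@dataclass
class RampRecording:
    """Repeated voltage-ramp sweeps before and during drug application."""

    sweep_times: np.ndarray  # s, one per sweep
    currents: np.ndarray     # (n_sweeps, n_v) pA
    v_grid: np.ndarray       # mV, −100..+100
    drug_onset: float        # s


@dataclass
class CellQC:
    """Inclusion decision for one recorded cell."""

    rmp: float
    has_ih: bool
    access_resistance: np.ndarray  # MΩ per monitor sweep
    passes: bool = False
    reasons: list[str] = field(default_factory=list)


# -- spikes and excitability ------------------------------------------------


def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = 0.0,
                  min_isi: float = 0.002,
                  window: tuple[float, float] | None = None) -> np.ndarray:
    """Spike times as upward threshold crossings separated by >= min_isi.

    ``window`` restricts counting to a time interval (the current step).
    """
    v = np.asarray(v, float)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = t[up]
    if window is not None:
        times = times[(times >= window[0]) & (times <= window[1])]
    kept = []
    for ts in times:
        if not kept or ts - kept[-1] >= min_isi:
            kept.append(ts)
    return np.asarray(kept)


def fi_curve(sweeps: SweepSet, threshold: float = 0.0, min_isi: float = 0.002,
             step_window: tuple[float, float] | None = None,
             cell_id: str = "", group: str = "") -> FICurve:
    """Count action potentials per current step of the F–I protocol."""
    if sweeps.mode != "current-clamp":
        raise ValueError("F–I analysis requires current-clamp sweeps")
    order = np.argsort(sweeps.sweep_labels)
    steps = np.asarray(sweeps.sweep_labels, float)[order]
    n_ap = np.array([detect_spikes(sweeps.t, sweeps.traces[i], threshold,
                                   min_isi, step_window).size
                     for i in order])
    return FICurve(steps=steps, n_ap=n_ap, cell_id=cell_id, group=group)


def rheobase(fi: FICurve) -> float | None:
    """Smallest injected current eliciting at least one spike."""
    nz = np.flatnonzero(fi.n_ap > 0)
    return float(fi.steps[nz[0]]) if nz.size else None


# -- quality control --------------------------------------------------------


def access_resistance_series(monitor: SweepSet, step_mv: float = -4.0,
                             baseline_window: tuple[float, float] = (0.0, 0.0),
                             step_onset: float | None = None) -> np.ndarray:
    """Ra per sweep from the −4 mV monitor step: Ra = ΔV / peak ΔI.

    Traces in pA; returns MΩ (Ra = |ΔV| mV / |ΔI| nA).
    """
    if step_onset is None:
        step_onset = float(monitor.t[len(monitor.t) // 2])
    pre = monitor.t < step_onset
    post = monitor.t >= step_onset
    ra = []
    for trace in monitor.traces:
        base = trace[pre].mean() if pre.any() else 0.0
        peak = np.max(np.abs(trace[post] - base))
        if peak == 0:
            raise ValueError("flat monitor trace: cannot compute Ra")
        ra.append(abs(step_mv) / (peak * 1e-3))  # mV / nA = MΩ
    return np.asarray(ra)


def cell_qc(rmp_trace: np.ndarray, ih_sweep: np.ndarray | None = None,
            ra_series_mohm: np.ndarray | None = None,
            sag_threshold: float = 0.1,
            ra_change_limit: float = 0.20) -> CellQC:
    """Apply the MSN inclusion rules.

    A cell passes when the resting membrane potential is below −60 mV,
    the −140 mV step shows no Ih sag (sag ratio <= ``sag_threshold``)
    and the access resistance never changes by more than
    ``ra_change_limit`` relative to its initial value.  The boundaries
    follow the stated rules: rmp = −60 mV fails (must be strictly
    lower); ΔRa exactly 20% passes (exclusion is for changes > 20%).

    ``ih_sweep`` is the response to the −140 mV step; the sag ratio is
    (peak − steady)/|peak| deflection, peak in the early fifth of the
    sweep and steady state in the final fifth.
    """
    rmp = float(np.mean(np.asarray(rmp_trace, float)))
    reasons = []
    if not rmp < -60.0:
        reasons.append(f"resting potential {rmp:.1f} mV not < -60 mV")

    has_ih = False
    if ih_sweep is not None:
        trace = np.asarray(ih_sweep, float)
        n = trace.size
        early = trace[: max(n // 5, 1)]
        late = trace[-max(n // 5, 1):]
        peak = early[np.argmax(np.abs(early))]
        steady = late.mean()
        if peak != 0:
            sag = (abs(peak) - abs(steady)) / abs(peak)
            has_ih = sag > sag_threshold
    if has_ih:
        reasons.append("Ih sag detected")

    ra = np.asarray(ra_series_mohm, float) if ra_series_mohm is not None else np.array([])
    if ra.size:
        change = np.max(np.abs(ra - ra[0])) / ra[0]
        if change > ra_change_limit:
            reasons.append(f"access resistance changed {change:.0%} > "
                           f"{ra_change_limit:.0%}")
    incomplete = ra_series_mohm is None
    if incomplete:
        reasons.append("QC incomplete: no access-resistance monitor")
    return CellQC(rmp=rmp, has_ih=has_ih, access_resistance=ra,
                  passes=not reasons, reasons=reasons)


# -- ramp-subtracted Trpv4 current ------------------------------------------


def trpv4_current(rec: RampRecording,
                  baseline_window: tuple[float, float],
                  drug_window: tuple[float, float]) -> pd.DataFrame:
    """Drug-subtracted I–V curve: mean baseline I(V) − mean drug I(V).

    The blocker-sensitive current is what the antagonist removed, so the
    subtraction is baseline minus drug, on the common voltage grid.
    Windows are half-open intervals [start, stop); each must contain at
    least 3 sweeps and must not straddle the drug-application time.
    """
    if baseline_window[1] > rec.drug_onset or drug_window[0] < rec.drug_onset:
        raise ValueError("analysis windows must not straddle the drug onset")
    tb = rec.sweep_times
    base = (tb >= baseline_window[0]) & (tb < baseline_window[1])
    drug = (tb >= drug_window[0]) & (tb < drug_window[1])
    if base.sum() < 3 or drug.sum() < 3:
        raise ValueError("need at least 3 sweeps per analysis window")
    iv = rec.currents[base].mean(axis=0) - rec.currents[drug].mean(axis=0)
    return pd.DataFrame({"v_mV": rec.v_grid, "i_pA": iv})


# -- synaptic ratios --------------------------------------------------------


def _amplitude(t: np.ndarray, trace: np.ndarray, stim: float,
               peak_window: tuple[float, float],
               baseline_window: tuple[float, float]) -> float:
    """Baseline-subtracted signed peak after a stimulus.

    Windows are relative to the stimulus time; the peak is the extremum
    of the baseline-subtracted trace within the peak window.
    """
    bsel = (t >= stim + baseline_window[0]) & (t < stim + baseline_window[1])
    psel = (t >= stim + peak_window[0]) & (t <= stim + peak_window[1])
    if not psel.any():
        raise ValueError("empty peak window")
    base = trace[bsel].mean() if bsel.any() else 0.0
    seg = trace[psel] - base
    return float(seg[np.argmax(np.abs(seg))])


def synaptic_metrics(sweeps: SweepSet, protocol: str,
                     peak_window: tuple[float, float] = (0.001, 0.020),
                     baseline_window: tuple[float, float] = (-0.010, 0.0),
                     nmda_window: tuple[float, float] = (0.045, 0.055),
                     e_rev: float = 0.0) -> dict[str, float]:
    """Synaptic ratios from voltage-clamp EPSC sweeps.

    protocol = 'ppr':
        paired stimuli (50 ms apart) at −60 mV; returns amp2/amp1.
    protocol = 'ampa_nmda':
        peak EPSC at −70 mV (AMPA-dominated) divided by the late-window
        mean at +35 mV (NMDA component, 45–55 ms post-stimulus).
    protocol = 'rectification':
        chord conductances g = I/(V − e_rev) from the peaks at −60 and
        +40 mV; returns g(−60)/g(+40).
    """
    if sweeps.mode != "voltage-clamp":
        raise ValueError("synaptic metrics require voltage-clamp sweeps")
    if sweeps.stim_onsets is None or len(sweeps.stim_onsets) == 0:
        raise ValueError("stim_onsets required for synaptic protocols")
    t = sweeps.t
    s0 = float(sweeps.stim_onsets[0])

    if protocol == "ppr":
        if len(sweeps.stim_onsets) < 2:
            raise ValueError("PPR requires two stimuli")
        s1 = float(sweeps.stim_onsets[1])
        trace = sweeps.traces[0]
        a1 = _amplitude(t, trace, s0, peak_window, baseline_window)
        a2 = _amplitude(t, trace, s1, peak_window, baseline_window)
        return {"amp1_pA": a1, "amp2_pA": a2, "ppr": abs(a2) / abs(a1)}

    if protocol == "ampa_nmda":
        try:
            tr_neg, tr_pos = sweeps.sweep(-70.0), sweeps.sweep(35.0)
        except KeyError as e:
            raise ValueError("AMPA/NMDA needs sweeps at -70 and +35 mV") from e
        ampa = _amplitude(t, tr_neg, s0, peak_window, baseline_window)
        bsel = (t >= s0 + baseline_window[0]) & (t < s0 + baseline_window[1])
        nsel = (t >= s0 + nmda_window[0]) & (t <= s0 + nmda_window[1])
        nmda = float(np.mean(tr_pos[nsel]) - (tr_pos[bsel].mean() if bsel.any() else 0.0))
        if nmda == 0:
            raise ValueError("zero NMDA component")
        return {"ampa_pA": ampa, "nmda_pA": nmda,
                "ampa_nmda": abs(ampa) / abs(nmda)}

    if protocol == "rectification":
        try:
            tr_neg, tr_pos = sweeps.sweep(-60.0), sweeps.sweep(40.0)
        except KeyError as e:
            raise ValueError("rectification needs sweeps at -60 and +40 mV") from e
        i_neg = _amplitude(t, tr_neg, s0, peak_window, baseline_window)
        i_pos = _amplitude(t, tr_pos, s0, peak_window, baseline_window)
        g_neg = i_neg / (-60.0 - e_rev)
        g_pos = i_pos / (40.0 - e_rev)
        if g_pos == 0:
            raise ValueError("zero chord conductance at +40 mV")
        return {"g_neg_nS": g_neg, "g_pos_nS": g_pos,
                "rectification_index": g_neg / g_pos}

    raise ValueError(f"unknown protocol {protocol!r}")
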