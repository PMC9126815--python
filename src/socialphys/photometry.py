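"""Fiber-photometry analysis: ΔF/F, PETHs and session z-scores.

The recording interleaves two excitation channels — 465 nm
(Ca²⁺-dependent GCaMP signal) and 405 nm (Ca²⁺-independent isosbestic
control) — by alternating the LEDs in a square pulse pattern while a
single photodetector is sampled at the raw rate.  Analysis proceeds as:

1. demultiplex the raw stream into one sample per LED pulse;
2. ΔF/F = (F − F0)/F0 with F0 the mean fluorescence over a baseline
   window (the last minutes of habituation, before stimuli appear);
3. align ΔF/F on proximity-entry events to build a peri-event time
   histogram (PETH);
4. z-score the PETH against the whole-session ΔF/F mean and SD, and
   summarise the [0; 5] s post-entry window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PhotometrySession:
    """Raw interleaved two-channel recording.

    ``fluor`` holds the photodetector output at ``raw_rate``;
    ``led_state`` labels each sample with the active LED
    (``"465"``, ``"405"`` or ``"off"``).  ``habituation_interval`` and
    ``test_interval`` are (start, stop) in seconds, habituation first.
    """

    t: np.ndarray
    fluor: np.ndarray
    led_state: np.ndarray
    raw_rate: float
    habituation_interval: tuple[float, float]
    test_interval: tuple[float, float]

    def __post_init__(self) -> None:
        if self.habituation_interval[1] > self.test_interval[0]:
            raise ValueError("habituation must precede the test interval")


@dataclass
class DffTrace:
    """ΔF/F at the demultiplexed rate."""

    t: np.ndarray
    dff: np.ndarray
    f0: float
    correction_mode: str = "none"  # 'none' | 'isosbestic'

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("ΔF/F contains non-finite values")


@dataclass
class Peth:
    """Event-aligned ΔF/F matrix on a relative time grid."""

    grid: np.ndarray          # relative time, contains 0
    rows: np.ndarray          # (n_events, n_bins)
    event_ids: list
    stimuli: list[str]
    dropped: list = field(default_factory=list)  # events outside recording

    @property
    def mean(self) -> np.ndarray:
        return self.rows.mean(axis=0)

    @property
    def n_events(self) -> int:
        return self.rows.shape[0]


@dataclass
class WindowStat:
    """Mean z-scored ΔF/F over the post-entry summary window."""

    mean_z: dict[str, float]          # per stimulus
    per_event: pd.DataFrame           # event id, stimulus, z
    mu: float                         # session ΔF/F mean used for z
    sigma: float                      # session ΔF/F SD used for z
    summary_window: tuple[float, float] = (0.0, 5.0)


# ---------------------------------------------------------------------------


def demultiplex(session: PhotometrySession,
                settle_discard: float = 0.2) -> dict[str, DffTrace | pd.DataFrame]:
    """Split the raw stream into per-channel traces, one value per pulse.

    Each contiguous run of a single LED state is one pulse; the leading
    ``settle_discard`` fraction of its samples is dropped (LED/detector
    settling) and the rest averaged.  The pulse timestamp is the centre
    of the pulse.  Off-state samples are ignored.

    Returns ``{"465": DataFrame(t, f), "405": DataFrame(t, f)}``.
    """
    led = np.asarray(session.led_state)
    if led.size != session.fluor.size:
        raise ValueError("led_state must label every raw sample")
    if not (0 <= settle_discard < 1):
        raise ValueError("settle_discard must be in [0, 1)")
    # contiguous runs of equal state
    change = np.flatnonzero(led[1:] != led[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [led.size]))
    out: dict[str, dict[str, list]] = {"465": {"t": [], "f": []},
                                       "405": {"t": [], "f": []}}
    for a, b in zip(starts, stops):
        state = str(led[a])
        if state not in out:
            continue
        k = a + int(np.floor((b - a) * settle_discard))
        if k >= b:
            raise ValueError("pulse with zero retained samples after settling")
        out[state]["t"].append(0.5 * (session.t[a] + session.t[b - 1]))
        out[state]["f"].append(float(np.mean(session.fluor[k:b])))
    return {ch: pd.DataFrame({"t": np.array(v["t"]), "f": np.array(v["f"])})
            for ch, v in out.items()}


def compute_dff(trace465: pd.DataFrame,
                f0_window: tuple[float, float],
                f0_statistic: str = "mean") -> DffTrace:
    """ΔF/F = (F − F0)/F0 with F0 the baseline statistic over a window.

    The baseline window is typically the last 5 min of habituation,
    before the stimuli are presented.
    """
    t = trace465["t"].to_numpy()
    f = trace465["f"].to_numpy()
    lo, hi = f0_window
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise ValueError("F0 window contains no samples")
    f0 = float(np.mean(f[sel]) if f0_statistic == "mean" else np.median(f[sel]))
    if f0 <= 0:
        raise ValueError("baseline F0 must be positive")
    return DffTrace(t=t, dff=(f - f0) / f0, f0=f0, correction_mode="none")


def isosbestic_correct(trace465: pd.DataFrame, trace405: pd.DataFrame,
                       fit_window: tuple[float, float] | None = None) -> DffTrace:
    """Motion-artifact correction using the isosbestic channel.

    The 405 nm trace is least-squares fitted (slope + intercept) to the
    465 nm trace over ``fit_window`` (whole recording when None), then
    ΔF/F = (F465 − fit405)/fit405.  Off by default in the pipeline —
    the plain baseline formula is the primary path — but useful when
    motion artifacts dominate.
    """
    t465 = trace465["t"].to_numpy()
    f465 = trace465["f"].to_numpy()
    f405 = np.interp(t465, trace405["t"].to_numpy(), trace405["f"].to_numpy())
    sel = np.ones_like(t465, bool)
    if fit_window is not None:
        sel = (t465 >= fit_window[0]) & (t465 <= fit_window[1])
    if np.var(f405[sel]) == 0:
        raise ValueError("degenerate isosbestic fit: zero variance in 405 channel")
    slope, intercept = np.polyfit(f405[sel], f465[sel], 1)
    fitted = slope * f405 + intercept
    if np.any(fitted <= 0):
        raise ValueError("fitted isosbestic baseline non-positive")
    return DffTrace(t=t465, dff=(f465 - fitted) / fitted, f0=float(np.mean(fitted)),
                    correction_mode="isosbestic")


def build_peth(dff: DffTrace, events: pd.DataFrame,
               window: tuple[float, float] = (-5.0, 10.0),
               bin_width: float | None = None) -> Peth:
    """Align ΔF/F on entry events to build the PETH.

    Only events flagged ``included`` are used.  Each row is the ΔF/F
    linearly interpolated onto the relative grid; events whose window
    extends beyond the recording are dropped and recorded in
    ``Peth.dropped``.  The grid step defaults to the median sampling
    interval of the ΔF/F trace.
    """
    pre, post = window
    if not (np.isfinite(pre) and np.isfinite(post) and pre <= 0 <= post and pre < post):
        raise ValueError("window must be finite and contain 0")
    if bin_width is None:
        bin_width = float(np.median(np.diff(dff.t)))
    # grid anchored at 0 so the entry bin is exactly t = 0
    neg = -np.arange(bin_width, -pre + 0.5 * bin_width, bin_width)[::-1]
    pos = np.arange(0.0, post + 0.5 * bin_width, bin_width)
    grid = np.concatenate((neg, pos))
    use = events[events["included"]] if "included" in events else events
    rows, ids, stimuli, dropped = [], [], [], []
    for idx, ev in use.iterrows():
        t0 = ev["t_entry"]
        if t0 + pre < dff.t[0] or t0 + post > dff.t[-1]:
            dropped.append(idx)
            continue
        rows.append(np.interp(t0 + grid, dff.t, dff.dff))
        ids.append(idx)
        stimuli.append(ev.get("stimulus", ""))
    if not rows:
        raise ValueError("no usable events for PETH")
    return Peth(grid=grid, rows=np.vstack(rows), event_ids=ids,
                stimuli=stimuli, dropped=dropped)


def peth_zscore_summary(peth: Peth, session_dff: DffTrace,
                        summary_window: tuple[float, float] = (0.0, 5.0),
                        session_interval: tuple[float, float] | None = None,
                        ) -> WindowStat:
    """z-score the PETH against the session ΔF/F and summarise [0; 5] s.

    z(bin) = (PETH mean(bin) − µ)/σ where µ and σ are the mean and SD of
    the whole-session ΔF/F (restricted to ``session_interval`` when
    given, e.g. the test phase).  ``mean_z`` per stimulus is the average
    z over the summary window; per-event z values are retained for
    paired statistics.
    """
    sel = np.ones_like(session_dff.t, bool)
    if session_interval is not None:
        sel = (session_dff.t >= session_interval[0]) & \
              (session_dff.t <= session_interval[1])
    mu = float(np.mean(session_dff.dff[sel]))
    sigma = float(np.std(session_dff.dff[sel]))
    if sigma == 0:
        raise ValueError("zero session variance: z-score undefined")
    lo, hi = summary_window
    in_win = (peth.grid >= lo) & (peth.grid <= hi)
    if not in_win.any():
        raise ValueError("summary window outside the PETH grid")
    per_event_mean = peth.rows[:, in_win].mean(axis=1)
    z_events = (per_event_mean - mu) / sigma
    per_event = pd.DataFrame({"event_id": peth.event_ids,
                              "stimulus": peth.stimuli, "z": z_events})
    mean_z = {stim: float(g["z"].mean())
              for stim, g in per_event.groupby("stimulus")}
    return WindowStat(mean_z=mean_z, per_event=per_event, mu=mu, sigma=sigma,
                      summary_window=summary_window)
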