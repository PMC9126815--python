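"""Three-chamber behavioural scoring from centre-point tracking.

Converts a tracked trajectory into zone occupancy, proximity-entry
events, exploration times and the social preference index
``social / (social + object)``, and applies the cohort inclusion rule
(animals exploring both enclosures for < 10 s in total are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import ArenaLayout

STIMULI = ("social", "object")


@dataclass
class TrackingTrace:
    """Timestamped centre-point coordinates of one session.

    ``t`` is strictly increasing, in seconds; ``x``/``y`` in cm within
    the arena.  ``phase`` optionally marks habituation vs test frames.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    phase: np.ndarray | None = None  # 'habituation' | 'test' per frame

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.t.size == 0:
            raise ValueError("empty tracking trace")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float) -> "TrackingTrace":
        return cls(df["t_s"].to_numpy(), df["x_cm"].to_numpy(),
                   df["y_cm"].to_numpy(), frame_rate)


@dataclass
class PreferenceResult:
    """Per-animal summary of the social preference test."""

    time_social: float
    time_object: float
    time_chambers: tuple[float, float, float]
    distance_moved: float
    preference_index: float | None = None
    included: bool = True
    exclusion_reason: str | None = None


def _frame_weights(t: np.ndarray) -> np.ndarray:
    """Per-frame dwell weight: the interval each sample represents.

    Each frame carries the forward inter-frame interval; the last frame
    carries the median interval so total time equals the session span.
    """
    dt = np.diff(t)
    med = np.median(dt) if dt.size else 0.0
    return np.append(dt, med)


def compute_occupancy(trace: TrackingTrace, layout: ArenaLayout) -> PreferenceResult:
    """Dwell time per proximity zone and chamber, plus distance moved.

    Zone membership uses the closed disc around each enclosure centre
    (a point on the boundary circle counts as inside).  Chamber times
    partition the total session time exactly.
    """
    w = _frame_weights(trace.t)
    times = {}
    for stim in STIMULI:
        inside = layout.in_zone(trace.x, trace.y, stim)
        times[stim] = float(np.sum(w[inside]))
    chamber = layout.chamber_of(trace.x)
    time_chambers = tuple(float(np.sum(w[chamber == k])) for k in range(3))
    dist = float(np.sum(np.hypot(np.diff(trace.x), np.diff(trace.y))))
    res = PreferenceResult(times["social"], times["object"], time_chambers, dist)
    total = times["social"] + times["object"]
    if total > 0:
        res.preference_index = preference_index(times["social"], times["object"])
    return res


def preference_index(time_social: float, time_object: float) -> float:
    """Social preference index ``social / (social + object)``; chance 0.5."""
    if time_social < 0 or time_object < 0:
        raise ValueError("exploration times must be non-negative")
    total = time_social + time_object
    if total == 0:
        raise ValueError("preference index undefined for zero total exploration")
    return time_social / total


def inclusion_filter(result: PreferenceResult,
                     min_total_exploration: float = 10.0) -> PreferenceResult:
    """Flag animals whose total enclosure exploration is below threshold.

    The boundary is kept: exactly ``min_total_exploration`` seconds is
    included (the exclusion rule is "less than" the threshold).
    """
    total = result.time_social + result.time_object
    if total < min_total_exploration:
        result.included = False
        result.exclusion_reason = (
            f"total exploration {total:.2f} s < {min_total_exploration:g} s"
        )
    else:
        result.included = True
        result.exclusion_reason = None
    return result


def detect_entries(trace: TrackingTrace, layout: ArenaLayout,
                   debounce: float = 0.5,
                   exclusion_windows: list[tuple[float, float]] | None = None,
                   ) -> pd.DataFrame:
    """Detect proximity-zone entry events for both stimuli.

    An entry is an outside→inside transition of the zone disc preceded
    by at least ``debounce`` seconds continuously outside; brief exits
    shorter than ``debounce`` are merged into the ongoing visit.  Events
    whose entry time falls inside an exclusion window are flagged
    (``included = False``) but retained with the reason.

    Returns a DataFrame with columns
    ``stimulus, t_entry, t_exit, included, reason`` sorted by entry
    time.  ``t_exit`` is NaN when the session ends inside the zone.
    """
    if debounce < 0:
        raise ValueError("debounce must be non-negative")
    exclusion_windows = exclusion_windows or []
    rows = []
    for stim in STIMULI:
        inside = np.asarray(layout.in_zone(trace.x, trace.y, stim))
        t = trace.t
        # raw transition indices
        trans = np.flatnonzero(np.diff(inside.astype(int)))
        entries, exits = [], []
        state = inside[0]
        if state:
            entries.append(t[0])
        for i in trans:
            if inside[i + 1]:
                entries.append(t[i + 1])
            else:
                exits.append(t[i + 1])
        if len(exits) < len(entries):
            exits.append(np.nan)
        # merge visits separated by an outside gap shorter than debounce
        merged: list[list[float]] = []
        for en, ex in zip(entries, exits):
            if merged and not np.isnan(merged[-1][1]) and en - merged[-1][1] < debounce:
                merged[-1][1] = ex
            else:
                merged.append([en, ex])
        for en, ex in merged:
            reason = None
            for lo, hi in exclusion_windows:
                if lo <= en <= hi:
                    reason = f"entry inside exclusion window [{lo:g}, {hi:g}] s"
                    break
            rows.append({"stimulus": stim, "t_entry": en, "t_exit": ex,
                         "included": reason is None, "reason": reason})
    events = pd.DataFrame(rows, columns=["stimulus", "t_entry", "t_exit",
                                         "included", "reason"])
    return events.sort_values("t_entry", ignore_index=True)
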