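"""Synthetic centre-point tracking with scheduled proximity-zone visits.

Emulates video-tracking output for the three-chamber task: a reflected
random walk confined to the arena, interrupted by scheduled visits to a
stimulus zone.  The visit schedule is the ground truth against which
entry detection and occupancy scoring are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..behavior import TrackingTrace
from ..layout import ArenaLayout


@dataclass
class SyntheticSessionTruth:
    """Ground truth of one simulated session."""

    true_entry_times_social: list[float] = field(default_factory=list)
    true_entry_times_object: list[float] = field(default_factory=list)
    event_response_amplitude: float = 0.0  # ΔF/F units
    response_latency: float = 0.0  # s
    decay_tau: float = 1.6  # s
    bleach_tau: float = np.inf  # s
    noise_sd: float = 0.0  # ΔF/F units
    seed: int = 0

    def __post_init__(self) -> None:
        for times in (self.true_entry_times_social, self.true_entry_times_object):
            if list(times) != sorted(times):
                raise ValueError("entry times must be sorted")
        if self.event_response_amplitude < 0:
            raise ValueError("response amplitude must be non-negative")


def simulate_tracking(layout: ArenaLayout, duration: float,
                      visit_schedule: list[tuple[str, float, float]] | None = None,
                      step_sd: float = 1.0, rate: float = 25.0,
                      seed: int = 0) -> tuple[TrackingTrace, SyntheticSessionTruth]:
    """Simulate a tracked trajectory with scheduled zone visits.

    Between visits the point performs a Gaussian random walk (step SD
    ``step_sd`` cm per frame) reflected at the arena walls and kept a
    small margin outside both proximity zones, so scheduled visits are
    the only zone entries.  During a scheduled ``(zone, start, stop)``
    interval the point sits inside the named zone (jittered around the
    enclosure centre), entering on the first frame at or after
    ``start``.

    Returns the trace and a truth record whose entry-time lists are the
    scheduled visit starts.
    """
    if rate <= 0:
        raise ValueError("frame rate must be positive")
    visit_schedule = sorted(visit_schedule or [], key=lambda v: v[1])
    for zone, start, stop in visit_schedule:
        if zone not in ("social", "object"):
            raise ValueError(f"unknown zone {zone!r}")
        if not (0 <= start < stop <= duration):
            raise ValueError("visit interval must lie inside [0, duration]")
        cx, cy = layout.enclosure_centers[zone]
        if not (0 <= cx <= layout.arena_w and 0 <= cy <= layout.arena_h):
            raise ValueError("zone centre outside arena")
    for (_, s1, e1), (_, s2, _) in zip(visit_schedule, visit_schedule[1:]):
        if s2 < e1:
            raise ValueError("visit intervals must not overlap")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.empty(n)
    y = np.empty(n)
    # start at the arena centre (centre chamber, outside both zones)
    px, py = layout.arena_w / 2.0, layout.arena_h / 2.0
    zr = layout.zone_radius
    margin = zr + 1.0  # keep the free walk this far from zone centres

    def scheduled_zone(ti: float) -> str | None:
        for zone, start, stop in visit_schedule:
            if start <= ti < stop:
                return zone
        return None

    for i in range(n):
        zone = scheduled_zone(t[i])
        if zone is not None:
            cx, cy = layout.enclosure_centers[zone]
            r = rng.uniform(0, 0.4 * zr)
            th = rng.uniform(0, 2 * np.pi)
            px, py = cx + r * np.cos(th), cy + r * np.sin(th)
        else:
            px += rng.normal(0, step_sd)
            py += rng.normal(0, step_sd)
            # reflect at walls
            px = _reflect(px, 0.0, layout.arena_w)
            py = _reflect(py, 0.0, layout.arena_h)
            # push out of (dilated) zones so free roaming never enters
            for stim in ("social", "object"):
                cx, cy = layout.enclosure_centers[stim]
                if np.hypot(px - cx, py - cy) < margin:
                    px, py = _nearest_outside(px, py, cx, cy, margin, layout)
        x[i], y[i] = px, py

    truth = SyntheticSessionTruth(
        true_entry_times_social=[s for z, s, _ in visit_schedule if z == "social"],
        true_entry_times_object=[s for z, s, _ in visit_schedule if z == "object"],
        seed=seed,
    )
    return TrackingTrace(t, x, y, frame_rate=rate), truth


def _nearest_outside(px: float, py: float, cx: float, cy: float,
                     margin: float, layout: ArenaLayout) -> tuple[float, float]:
    """Closest point at distance ``margin`` from (cx, cy) inside the arena.

    The proximity zone can be clipped by a wall (its diameter exceeds
    the chamber width), so the radial push-out may leave the arena; in
    that case scan angles outward from the radial direction and take the
    first in-bounds candidate.
    """
    theta = np.arctan2(py - cy, px - cx) if (px, py) != (cx, cy) else 0.0
    for k in range(0, 37):
        for sign in (1, -1) if k else (1,):
            a = theta + sign * k * np.pi / 36.0
            qx, qy = cx + margin * np.cos(a), cy + margin * np.sin(a)
            if 0 <= qx <= layout.arena_w and 0 <= qy <= layout.arena_h:
                return qx, qy
    return px, py  # unreachable for sane layouts


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return lo + v
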