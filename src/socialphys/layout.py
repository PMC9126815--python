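"""Arena geometry for the three-chamber sociability task.

The apparatus is a rectangular arena divided into three equal-width
chambers along x.  Two wire-mesh enclosures sit in the centres of the
outer chambers; one holds the social stimulus (a juvenile mouse), the
other stays empty and serves as the inanimate object.  A circular
"proximity zone" is drawn around each enclosure: its diameter is the
enclosure diameter plus a fixed margin, so an entry into the zone is an
approach to the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ArenaLayout:
    """Geometry of the three-chamber arena, in centimetres.

    Parameters
    ----------
    arena_w, arena_h:
        Outer dimensions of the floor (default 60 x 40 cm).
    enclosure_dims:
        Footprint of each enclosure (default 16 x 9 cm).  The rectangle
        is reduced to a circle of diameter ``max(enclosure_dims)`` when
        deriving the proximity zone.
    zone_margin:
        Added to the enclosure diameter to obtain the zone diameter
        (default 5 cm, giving a 21 cm zone for a 16 x 9 enclosure).
    zone_diameter:
        Explicit zone diameter; overrides the derivation when not None.
    social_side:
        ``"left"`` or ``"right"``; which outer chamber holds the social
        stimulus (counterbalanced across animals in practice).
    """

    arena_w: float = 60.0
    arena_h: float = 40.0
    enclosure_dims: tuple[float, float] = (16.0, 9.0)
    zone_margin: float = 5.0
    zone_diameter: float | None = None
    social_side: str = "left"

    def __post_init__(self) -> None:
        if self.arena_w <= 0 or self.arena_h <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.social_side not in ("left", "right"):
            raise ValueError("social_side must be 'left' or 'right'")
        zr = self.zone_radius
        cx = min(c[0] for c in self.enclosure_centers.values())
        if not (0 < cx < self.arena_w):
            raise ValueError("enclosure centres must lie inside the arena")

    # -- derived geometry -------------------------------------------------

    @property
    def chamber_bounds(self) -> list[tuple[float, float]]:
        """Three equal x-intervals partitioning the arena width."""
        w = self.arena_w / 3.0
        return [(0.0, w), (w, 2 * w), (2 * w, self.arena_w)]

    @property
    def enclosure_centers(self) -> dict[str, tuple[float, float]]:
        """Centres of the social and object enclosures (outer chambers)."""
        w = self.arena_w / 3.0
        y = self.arena_h / 2.0
        left, right = (w / 2.0, y), (self.arena_w - w / 2.0, y)
        if self.social_side == "left":
            return {"social": left, "object": right}
        return {"social": right, "object": left}

    @property
    def zone_radius(self) -> float:
        if self.zone_diameter is not None:
            return self.zone_diameter / 2.0
        return (max(self.enclosure_dims) + self.zone_margin) / 2.0

    # -- membership predicates -------------------------------------------

    def in_zone(self, x, y, stimulus: str):
        """Closed-disc membership of point(s) in a proximity zone."""
        cx, cy = self.enclosure_centers[stimulus]
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.zone_radius**2

    def chamber_of(self, x) -> int:
        """Chamber index (0 = left, 1 = centre, 2 = right) of x position(s)."""
        import numpy as np

        w = self.arena_w / 3.0
        return np.clip((np.asarray(x) // w).astype(int), 0, 2)
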