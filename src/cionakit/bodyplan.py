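"""Landmark layout of the tracked adult Ciona body.

Eighteen contour points are tracked per animal: four around each siphon
(dorsal/ventral rim and dorsal/ventral base) and ten along the trunk from
the neck down to the holdfast and back.  The :class:`BodyPlan` records which
indices form the siphon width pairs, the four-point siphon area contours,
the full closed body outline, and the trunk polygon (outline minus the
siphon rim points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["BodyPlan", "DEFAULT_LANDMARKS", "default_body_plan"]

#: Canonical landmark order: a single closed walk around the body outline.
DEFAULT_LANDMARKS: tuple[str, ...] = (
    "OS_base_dorsal",      # 0
    "OS_rim_dorsal",       # 1
    "OS_rim_ventral",      # 2
    "OS_base_ventral",     # 3
    "neck_ventral",        # 4
    "AS_base_ventral",     # 5
    "AS_rim_ventral",      # 6
    "AS_rim_dorsal",       # 7
    "AS_base_dorsal",      # 8
    "trunk_ventral_upper", # 9
    "trunk_ventral_mid",   # 10
    "trunk_ventral_lower", # 11
    "holdfast",            # 12
    "trunk_dorsal_lower",  # 13
    "trunk_dorsal_mid",    # 14
    "trunk_dorsal_upper",  # 15
    "neck_dorsal_lower",   # 16
    "neck_dorsal",         # 17
)


@dataclass(frozen=True)
class BodyPlan:
    """Index bookkeeping for the 18 tracked body points.

    Attributes
    ----------
    landmark_names:
        Ordered names of the 18 tracked points.
    os_width_pair, as_width_pair:
        Dorsal/ventral rim indices of the oral and atrial siphon; their
        Euclidean distance is the siphon opening width.
    os_quad, as_quad:
        Four-point contours enclosing each siphon area (rims plus bases).
    body_polygon:
        Ordered indices of the full closed outline (each index once).
    trunk_polygon:
        Outline indices excluding the siphon rim points.
    """

    landmark_names: tuple[str, ...] = DEFAULT_LANDMARKS
    os_width_pair: tuple[int, int] = (1, 2)
    as_width_pair: tuple[int, int] = (6, 7)
    os_quad: tuple[int, int, int, int] = (0, 1, 2, 3)
    as_quad: tuple[int, int, int, int] = (5, 6, 7, 8)
    body_polygon: tuple[int, ...] = tuple(range(18))
    trunk_polygon: tuple[int, ...] = field(
        default=(0, 3, 4, 5, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17)
    )

    def __post_init__(self) -> None:
        n = len(self.landmark_names)
        if n != 18:
            raise ValueError(f"expected 18 landmarks, got {n}")
        for idx in (*self.os_width_pair, *self.as_width_pair,
                    *self.os_quad, *self.as_quad,
                    *self.body_polygon, *self.trunk_polygon):
            if not 0 <= idx < n:
                raise ValueError(f"landmark index {idx} out of range")
        if not set(self.os_width_pair) <= set(self.os_quad):
            raise ValueError("os_quad must contain os_width_pair")
        if not set(self.as_width_pair) <= set(self.as_quad):
            raise ValueError("as_quad must contain as_width_pair")
        if sorted(self.body_polygon) != list(range(n)):
            raise ValueError("body_polygon must use each index exactly once")
        rims = set(self.os_width_pair) | set(self.as_width_pair)
        if set(self.trunk_polygon) & rims:
            raise ValueError("trunk_polygon may not contain siphon rim points")

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    def index_of(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise KeyError(f"unknown landmark {name!r}") from None


def default_body_plan() -> BodyPlan:
    """The standard 18-point plan used throughout the package."""
    return BodyPlan()
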