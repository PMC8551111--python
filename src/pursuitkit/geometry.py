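"""Pitch geometry and experimental constants.

The play area ("pitch") is a rectangle centered at the origin. X is the
horizontal (width) axis and Y the vertical axis; the attacker starts near
the top edge at (0, +height/2 - margin), the defender at the center, and
the end line the attacker tries to reach is Y = -height/2.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Condition(str, Enum):
    """Pitch-width condition."""

    narrow = "narrow"
    square = "square"
    wide = "wide"


#: Pitch width (cm) per condition; the mapping is bijective.
CONDITION_WIDTH_CM: dict[Condition, float] = {
    Condition.narrow: 7.5,
    Condition.square: 15.0,
    Condition.wide: 30.0,
}

#: Number of equal-width columns used for spatial binning per condition.
CONDITION_N_COLUMNS: dict[Condition, int] = {
    Condition.narrow: 4,
    Condition.square: 8,
    Condition.wide: 16,
}

PITCH_HEIGHT_CM: float = 15.0
DISK_DIAMETER_CM: float = 1.0
MAX_SPEED_CMPS: float = 5.5

#: Native recording rate (Hz) and the analysis rate used for heading /
#: model work (Hz).
RECORD_RATE_HZ: float = 120.0
ANALYSIS_RATE_HZ: float = 20.0

#: Matched defender responses are kept only within this latency window (s).
MAX_RESPONSE_LATENCY_S: float = 0.5
#: Responses faster than this are classified as short latency (s).
SHORT_LATENCY_S: float = 0.150


@dataclass(frozen=True)
class PitchGeometry:
    """Rectangle bounds plus agent disk size and speed cap."""

    width: float
    height: float = PITCH_HEIGHT_CM
    disk_diameter: float = DISK_DIAMETER_CM
    max_speed: float = MAX_SPEED_CMPS

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("pitch dimensions must be positive")

    @classmethod
    def for_condition(cls, condition: Condition | str) -> "PitchGeometry":
        return cls(width=CONDITION_WIDTH_CM[Condition(condition)])

    @property
    def condition(self) -> Condition:
        for cond, width in CONDITION_WIDTH_CM.items():
            if width == self.width:
                return cond
        raise ValueError(f"width {self.width} cm matches no condition")

    @property
    def half_width(self) -> float:
        return self.width / 2.0

    @property
    def half_height(self) -> float:
        return self.height / 2.0

    def contains(self, x: float, y: float, margin: float = 0.0) -> bool:
        """True if (x, y) lies inside the pitch shrunk by ``margin``."""
        return (
            -self.half_width + margin <= x <= self.half_width - margin
            and -self.half_height + margin <= y <= self.half_height - margin
        )


def n_columns_for(condition: Condition | str) -> int:
    return CONDITION_N_COLUMNS[Condition(condition)]
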