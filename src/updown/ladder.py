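"""Filament ladders for the four supported up-down assays.

A ladder is the ordered set of von Frey forces printed on one scoring
table, together with the log-unit value of each filament, the log-step
``delta`` used by the Dixon formula, and the index of the starting
(mid-range) filament.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Assay",
    "FilamentLadder",
    "build_ladder",
    "grams_to_log_units",
    "grams_to_millinewtons",
    "UnsupportedAssayError",
]

#: Standard gravity, mN per gram-force.
MILLINEWTONS_PER_GRAM = 9.80665


class UnsupportedAssayError(ValueError):
    """Raised for an assay name outside the supported set."""


class Assay(str, enum.Enum):
    MOUSE = "mouse"
    RAT = "rat"
    HUMAN_MDT = "human_mdt"
    HUMAN_MPT = "human_mpt"

    @classmethod
    def coerce(cls, value: "Assay | str") -> "Assay":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower().replace("-", "_"))
        except ValueError:
            raise UnsupportedAssayError(
                f"unsupported assay {value!r}; expected one of "
                f"{[a.value for a in cls]}"
            ) from None


def grams_to_log_units(force_g: float) -> float:
    """Log-unit value of a force: log10 of the force in 0.1 mg units.

    This is the handle-marking convention of commercial filament sets,
    i.e. ``log10(10000 * grams)``; a kappa of zero then maps the final
    filament back to its own force exactly.
    """
    if force_g <= 0:
        raise ValueError(f"force must be positive, got {force_g}")
    return math.log10(10000.0 * force_g)


def grams_to_millinewtons(force_g: float) -> float:
    """Convert gram-force to millinewtons using standard gravity."""
    return force_g * MILLINEWTONS_PER_GRAM


@dataclass(frozen=True)
class FilamentLadder:
    """Ordered force set for one assay.

    Attributes
    ----------
    assay : Assay
    forces_g : tuple of float
        Strictly increasing filament forces in grams.
    delta : float
        Log-unit step used in the Dixon formula (printed constant).
    start_index : int
        1-based index of the filament presented first.
    """

    assay: Assay
    forces_g: tuple[float, ...]
    delta: float
    start_index: int
    log_units: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.forces_g, self.forces_g[1:])):
            raise ValueError("forces_g must be strictly increasing")
        if not 1 <= self.start_index <= len(self.forces_g):
            raise ValueError("start_index out of range")
        object.__setattr__(
            self,
            "log_units",
            tuple(grams_to_log_units(f) for f in self.forces_g),
        )

    @property
    def n_filaments(self) -> int:
        return len(self.forces_g)

    @property
    def start_force_g(self) -> float:
        return self.forces_g[self.start_index - 1]

    @property
    def mean_log_step(self) -> float:
        """Mean of successive log-unit differences (ladder-derived delta)."""
        diffs = [b - a for a, b in zip(self.log_units, self.log_units[1:])]
        return sum(diffs) / len(diffs)

    @property
    def max_log_step(self) -> float:
        return max(b - a for a, b in zip(self.log_units, self.log_units[1:]))

    def force(self, index: int) -> float:
        """Force in grams of the 1-based filament index."""
        if not 1 <= index <= self.n_filaments:
            raise IndexError(f"filament index {index} out of range")
        return self.forces_g[index - 1]


# Force sets: standard commercial von Frey filaments restricted to the
# printed range of each sheet.  delta is the printed per-assay constant;
# the ladder-derived mean log step agrees for mouse/rat/MPT (MDT differs
# in the third decimal and the printed value wins).
_LADDERS: dict[Assay, FilamentLadder] = {
    Assay.MOUSE: FilamentLadder(
        Assay.MOUSE,
        (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0, 4.0),
        delta=0.25,
        start_index=5,
    ),
    Assay.RAT: FilamentLadder(
        Assay.RAT,
        (0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0),
        delta=0.17,
        start_index=5,
    ),
    Assay.HUMAN_MDT: FilamentLadder(
        Assay.HUMAN_MDT,
        (0.02, 0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4),
        delta=0.25,
        start_index=5,
    ),
    Assay.HUMAN_MPT: FilamentLadder(
        Assay.HUMAN_MPT,
        (4.0, 6.0, 8.0, 10.0, 15.0, 26.0, 60.0, 100.0, 180.0),
        delta=0.21,
        start_index=3,
    ),
}


def build_ladder(assay: Assay | str) -> FilamentLadder:
    """Return the bundled filament ladder for *assay*."""
    return _LADDERS[Assay.coerce(assay)]
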