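"""Per-pulse liquid replacement in a chamber cascade.

One pulse of defined flow speed and duration exchanges a fixed fraction of
each chamber's liquid with the inlet stream; downstream chambers exchange
less, which is what creates the concentration gradient. The calibrated
default profile is (0.2248, 0.2003, 0.1716, 0.1387, 0.1128) for a 4 s pulse
at 5 mm/s. A pulse applied to chamber concentration c gives

    c' = (1 - f) * c + f * c_inlet

per chamber, so repeated identical pulses approach the inlet concentration
monotonically with the closed form c_inlet * (1 - (1 - f)^n).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ShapeError, ValidationError

__all__ = [
    "Path",
    "ReplacementProfile",
    "PulseEvent",
    "ConcentrationState",
    "default_profile",
    "oriented_fractions",
    "apply_pulse",
    "run_schedule",
    "steady_state_limit",
]


class Path(enum.Enum):
    """Flow direction through a chamber array.

    PATH1 enters at chamber 1 (top-down); PATH2 is the opposite direction,
    so chamber m sees the highest exchange.
    """

    PATH1 = "path1"
    PATH2 = "path2"

    @classmethod
    def parse(cls, value: "Path | str | int") -> "Path":
        if isinstance(value, Path):
            return value
        if isinstance(value, int):
            value = f"path{value}"
        text = str(value).strip().lower().replace("-", "").replace("_", "")
        if text in ("path1", "1", "top", "topdown"):
            return cls.PATH1
        if text in ("path2", "2", "bottom", "bottomup"):
            return cls.PATH2
        raise ValidationError(f"cannot parse path {value!r}")


#: Monotonicity slack for profiles produced by iterative solvers.
_MONOTONE_TOL = 1e-12


@dataclass(frozen=True)
class ReplacementProfile:
    """Per-chamber liquid-replacement fractions for one pulse.

    ``fractions[0]`` is the chamber nearest the pulse entry. Fractions are
    strictly in (0, 1) and non-increasing: downstream chambers exchange less.
    """

    flow_speed_mm_s: float
    duration_s: float
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.flow_speed_mm_s <= 0:
            raise ValidationError(
                f"flow_speed_mm_s must be > 0, got {self.flow_speed_mm_s}"
            )
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        if not self.fractions:
            raise ValidationError("fractions must be non-empty")
        object.__setattr__(self, "fractions", tuple(float(f) for f in self.fractions))
        for i, f in enumerate(self.fractions, start=1):
            if not 0.0 < f < 1.0:
                raise ValidationError(
                    f"fraction for chamber {i} must lie strictly in (0, 1), got {f}"
                )
        diffs = np.diff(self.fractions)
        if np.any(diffs > _MONOTONE_TOL):
            raise ValidationError("fractions must be non-increasing along the cascade")

    @property
    def n_chambers(self) -> int:
        return len(self.fractions)


#: Calibrated replacement fractions for a 4 s pulse at 5 mm/s.
DEFAULT_FRACTIONS = (0.2248, 0.2003, 0.1716, 0.1387, 0.1128)


def default_profile() -> ReplacementProfile:
    """The calibrated five-chamber profile at 5 mm/s for 4 s."""
    return ReplacementProfile(
        flow_speed_mm_s=5.0, duration_s=4.0, fractions=DEFAULT_FRACTIONS
    )


def oriented_fractions(profile: ReplacementProfile, path: Path | str) -> tuple[float, ...]:
    """Fractions in fixed chamber order 1..m for the given flow direction.

    PATH1 returns the stored order; PATH2 reverses it (the chip layout is
    mirror-symmetric, so the reverse pulse sees the mirrored cascade).
    """
    path = Path.parse(path)
    if path is Path.PATH1:
        return profile.fractions
    return tuple(reversed(profile.fractions))


@dataclass(frozen=True)
class PulseEvent:
    """One pulse of a single species along one channel and direction."""

    species: str
    channel: int
    path: Path
    inlet_concentration: float  # ng/mL
    profile: ReplacementProfile

    def __post_init__(self) -> None:
        if self.inlet_concentration < 0:
            raise ValidationError(
                f"inlet_concentration must be >= 0, got {self.inlet_concentration}"
            )
        object.__setattr__(self, "path", Path.parse(self.path))


@dataclass(frozen=True)
class ConcentrationState:
    """Per-chamber, per-species concentrations (ng/mL) at an elapsed time."""

    species: tuple[str, ...]
    concentrations: np.ndarray  # shape (n_chambers, n_species), ng/mL
    time_s: float = 0.0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 2 or conc.shape[1] != len(self.species):
            raise ShapeError(
                f"concentrations must have shape (n_chambers, {len(self.species)}), "
                f"got {conc.shape}"
            )
        if np.any(conc < 0):
            raise ValidationError("concentrations must be >= 0")
        conc.flags.writeable = False
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "species", tuple(self.species))

    @classmethod
    def blank(cls, n_chambers: int, species: Iterable[str]) -> "ConcentrationState":
        species = tuple(species)
        return cls(species, np.zeros((n_chambers, len(species))), time_s=0.0)

    @property
    def n_chambers(self) -> int:
        return self.concentrations.shape[0]

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not registered in state") from None

    def value(self, chamber: int, species: str) -> float:
        """Concentration in 1-based ``chamber`` for ``species``."""
        if not 1 <= chamber <= self.n_chambers:
            raise KeyError(f"chamber {chamber} outside 1..{self.n_chambers}")
        return float(self.concentrations[chamber - 1, self.species_index(species)])


def apply_pulse(state: ConcentrationState, pulse: PulseEvent) -> ConcentrationState:
    """Mix one pulse into the cascade: c' = (1 - f) c + f c_inlet per chamber.

    Only the pulsed species changes (channels do not cross-talk); time
    advances by the pulse duration.
    """
    if state.n_chambers != pulse.profile.n_chambers:
        raise ShapeError(
            f"state has {state.n_chambers} chambers but profile has "
            f"{pulse.profile.n_chambers}"
        )
    j = state.species_index(pulse.species)
    fractions = np.array(oriented_fractions(pulse.profile, pulse.path))
    conc = state.concentrations.copy()
    conc[:, j] = (1.0 - fractions) * conc[:, j] + fractions * pulse.inlet_concentration
    return ConcentrationState(
        species=state.species,
        concentrations=conc,
        time_s=state.time_s + pulse.profile.duration_s,
    )


def run_schedule(
    state: ConcentrationState, pulses: Sequence[PulseEvent]
) -> list[ConcentrationState]:
    """Apply pulses in order; returns the trajectory including the start state."""
    trajectory = [state]
    for pulse in pulses:
        state = apply_pulse(state, pulse)
        trajectory.append(state)
    return trajectory


def steady_state_limit(pulse: PulseEvent, n_pulses: int) -> ConcentrationState:
    """Closed form of n identical pulses from a drug-free cascade.

    Chamber i reaches c_inlet * (1 - (1 - f_i)^n); equal to the n-fold
    apply_pulse recurrence.
    """
    if n_pulses < 0:
        raise ValidationError(f"n_pulses must be >= 0, got {n_pulses}")
    fractions = np.array(oriented_fractions(pulse.profile, pulse.path))
    conc = pulse.inlet_concentration * (1.0 - (1.0 - fractions) ** n_pulses)
    return ConcentrationState(
        species=(pulse.species,),
        concentrations=conc[:, None],
        time_s=n_pulses * pulse.profile.duration_s,
    )
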