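"""Per-chamber dose gradients, reported values, and combination dose matrices.

A drug pulsed along PATH1 is highest in chamber 1 (rank 1) and lowest in
chamber m; PATH2 mirrors the ranks. A chamber's combination code is the
tuple of per-drug ranks, rendered "1 + 5 + 5" for high + low + low.

Reported concentrations follow the chip's reporting convention: values are
rounded to the nearest 1% of the inlet concentration (half away from zero).
Raw unrounded concentrations are always retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigurationError, ValidationError
from .layout import ChipLayout
from .transport import Path, ReplacementProfile, oriented_fractions

__all__ = [
    "DrugSpec",
    "DoseMatrix",
    "chamber_concentrations",
    "report_rounded",
    "combination_matrix",
    "plan_experiment",
    "IDLE",
]


@dataclass(frozen=True)
class DrugSpec:
    """One drug feeding one channel of an array at a fixed inlet concentration."""

    name: str
    inlet_concentration: float  # ng/mL
    channel: int

    def __post_init__(self) -> None:
        if self.inlet_concentration <= 0:
            raise ValidationError(
                f"inlet_concentration must be > 0, got {self.inlet_concentration}"
            )
        if self.channel < 1:
            raise ValidationError(f"channel must be >= 1, got {self.channel}")


def chamber_concentrations(
    drug: DrugSpec, profile: ReplacementProfile, path: Path | str
) -> tuple[float, ...]:
    """Concentration in chambers 1..m after one pulse into drug-free chambers."""
    fractions = oriented_fractions(profile, path)
    return tuple(drug.inlet_concentration * f for f in fractions)


def report_rounded(value: float, inlet_concentration: float) -> float:
    """Round to the nearest multiple of 1% of the inlet, half away from zero."""
    if inlet_concentration <= 0:
        raise ValidationError(
            f"inlet_concentration must be > 0, got {inlet_concentration}"
        )
    if value < 0:
        raise ValidationError(f"value must be >= 0, got {value}")
    step = inlet_concentration / 100.0
    return math.floor(value / step + 0.5) * step


@dataclass(frozen=True)
class DoseMatrix:
    """Planned per-chamber doses for a set of drugs on one array.

    Row r is chamber r (1-based); ``ranks[r-1, d]`` is drug d's dose rank in
    that chamber (1 = highest). ``concentrations`` are exact values,
    ``reported`` the 1%-of-inlet rounded ones.
    """

    drugs: tuple[DrugSpec, ...]
    paths: tuple[Path, ...]
    ranks: np.ndarray  # (m, n_drugs) int
    concentrations: np.ndarray  # (m, n_drugs) ng/mL
    reported: np.ndarray  # (m, n_drugs) ng/mL

    @property
    def n_chambers(self) -> int:
        return self.ranks.shape[0]

    def combo_code(self, chamber: int) -> tuple[int, ...]:
        """Per-drug rank tuple for a 1-based chamber index."""
        if not 1 <= chamber <= self.n_chambers:
            raise KeyError(f"chamber {chamber} outside 1..{self.n_chambers}")
        return tuple(int(r) for r in self.ranks[chamber - 1])

    def combo_label(self, chamber: int) -> str:
        """Human-readable code, e.g. '1 + 5 + 5'."""
        return " + ".join(str(r) for r in self.combo_code(chamber))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (chamber, drug)."""
        rows = []
        for r in range(1, self.n_chambers + 1):
            label = self.combo_label(r)
            for d, drug in enumerate(self.drugs):
                rows.append(
                    {
                        "chamber": r,
                        "drug": drug.name,
                        "rank": int(self.ranks[r - 1, d]),
                        "concentration_ng_per_mL": float(self.concentrations[r - 1, d]),
                        "reported_ng_per_mL": float(self.reported[r - 1, d]),
                        "combo_code": label,
                    }
                )
        return pd.DataFrame(rows)


def combination_matrix(
    drugs: list[DrugSpec],
    paths: dict[str, Path | str],
    profile: ReplacementProfile,
) -> DoseMatrix:
    """Build the combination dose matrix for drugs with per-drug directions.

    Drugs are ordered by channel index; each must occupy a distinct channel
    and have a direction assigned.
    """
    if not drugs:
        raise ConfigurationError("at least one drug is required")
    channels = [d.channel for d in drugs]
    if len(set(channels)) != len(channels):
        raise ConfigurationError(f"drugs share a channel: {sorted(channels)}")
    for drug in drugs:
        if drug.name not in paths:
            raise ConfigurationError(f"no path assigned for drug {drug.name!r}")
    ordered = sorted(drugs, key=lambda d: d.channel)
    parsed = tuple(Path.parse(paths[d.name]) for d in ordered)
    m = profile.n_chambers

    ranks = np.empty((m, len(ordered)), dtype=int)
    conc = np.empty((m, len(ordered)))
    rep = np.empty((m, len(ordered)))
    for d, (drug, path) in enumerate(zip(ordered, parsed)):
        values = chamber_concentrations(drug, profile, path)
        for r in range(1, m + 1):
            ranks[r - 1, d] = r if path is Path.PATH1 else m + 1 - r
            conc[r - 1, d] = values[r - 1]
            rep[r - 1, d] = report_rounded(values[r - 1], drug.inlet_concentration)
    return DoseMatrix(
        drugs=tuple(ordered), paths=parsed, ranks=ranks, concentrations=conc, reported=rep
    )


#: Marker for arrays left without a condition.
IDLE = "idle"


def plan_experiment(layout: ChipLayout, conditions: list[str]) -> dict[int, str]:
    """Assign named conditions to arrays 1..n in listed order.

    Arrays beyond the condition list are marked idle. More conditions than
    arrays is a capacity error.
    """
    if len(conditions) > layout.n_arrays:
        raise CapacityError(
            f"{len(conditions)} conditions exceed {layout.n_arrays} arrays"
        )
    assignment: dict[int, str] = {}
    for i in range(1, layout.n_arrays + 1):
        assignment[i] = conditions[i - 1] if i <= len(conditions) else IDLE
    return assignment


def assignment_to_frame(assignment: dict[int, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"array": list(assignment), "condition": list(assignment.values())}
    )


def assignment_from_frame(frame: pd.DataFrame) -> dict[int, str]:
    return {int(row.array): str(row.condition) for row in frame.itertuples()}
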