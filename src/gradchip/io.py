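"""Config-document and table I/O.

Structured configs are YAML (JSON is a YAML subset and also accepted);
tables are comma-separated text.
"""

from __future__ import annotations

from pathlib import Path as FilePath
from typing import Any, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError
from .layout import ChipLayout
from .planner import DrugSpec
from .response import ResponseModel
from .transport import (
    ConcentrationState,
    Path,
    PulseEvent,
    ReplacementProfile,
    default_profile,
)

__all__ = [
    "load_layout",
    "save_layout",
    "parse_profile",
    "load_schedule",
    "load_plan_config",
    "load_response_model",
    "trajectory_to_frame",
    "read_cells",
    "write_table",
]


def _load_document(path: "str | FilePath") -> Any:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_layout(path: "str | FilePath") -> ChipLayout:
    return ChipLayout.from_dict(_load_document(path))


def save_layout(layout: ChipLayout, path: "str | FilePath") -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout.to_dict(), fh, sort_keys=False)


def parse_profile(spec: Any) -> ReplacementProfile:
    """Resolve a profile reference: "default" or an explicit mapping."""
    if spec in (None, "default"):
        return default_profile()
    if isinstance(spec, dict):
        return ReplacementProfile(
            flow_speed_mm_s=spec.get("flow_speed_mm_s", 5.0),
            duration_s=spec.get("duration_s", 4.0),
            fractions=tuple(spec["fractions"]),
        )
    raise ConfigurationError(f"cannot parse profile reference {spec!r}")


def load_schedule(path: "str | FilePath") -> tuple[list[PulseEvent], ConcentrationState]:
    """Read a pulse schedule and build its initial drug-free state.

    Document shape::

        profile: default        # or {flow_speed_mm_s, duration_s, fractions}
        pulses:
          - {species: EGF, channel: 1, path: path1,
             inlet_ng_per_ml: 500, repeats: 1}
    """
    doc = _load_document(path)
    if not isinstance(doc, dict) or "pulses" not in doc:
        raise ConfigurationError("schedule document must contain a 'pulses' list")
    profile = parse_profile(doc.get("profile"))
    pulses: list[PulseEvent] = []
    for entry in doc["pulses"]:
        pulse = PulseEvent(
            species=str(entry["species"]),
            channel=int(entry.get("channel", 1)),
            path=Path.parse(entry.get("path", "path1")),
            inlet_concentration=float(entry["inlet_ng_per_ml"]),
            profile=parse_profile(entry.get("profile", doc.get("profile"))),
        )
        pulses.extend([pulse] * int(entry.get("repeats", 1)))
    species = tuple(dict.fromkeys(p.species for p in pulses))
    state = ConcentrationState.blank(profile.n_chambers, species)
    return pulses, state


def load_plan_config(
    path: "str | FilePath",
) -> tuple[list[DrugSpec], dict[str, Path], ReplacementProfile]:
    """Read a combination-plan document: drugs, per-drug paths, profile."""
    doc = _load_document(path)
    if not isinstance(doc, dict) or "drugs" not in doc:
        raise ConfigurationError("plan document must contain a 'drugs' list")
    profile = parse_profile(doc.get("profile"))
    drugs: list[DrugSpec] = []
    paths: dict[str, Path] = {}
    for entry in doc["drugs"]:
        drug = DrugSpec(
            name=str(entry["name"]),
            inlet_concentration=float(entry["inlet_ng_per_ml"]),
            channel=int(entry["channel"]),
        )
        drugs.append(drug)
        paths[drug.name] = Path.parse(entry.get("path", "path1"))
    return drugs, paths, profile


def load_response_model(path: "str | FilePath") -> tuple[ResponseModel, int]:
    """Read a synthetic response model; returns (model, cells_per_chamber)."""
    doc = _load_document(path)
    model = ResponseModel(
        baseline_differentiation=float(doc["baseline_differentiation"]),
        max_differentiation=float(doc["max_differentiation"]),
        dose_midpoint=float(doc["dose_midpoint_ng_per_ml"]),
        steepness=float(doc["steepness"]),
        seed=int(doc.get("seed", 0)),
    )
    return model, int(doc.get("cells_per_chamber", 100))


def trajectory_to_frame(trajectory: Sequence[ConcentrationState]) -> pd.DataFrame:
    """Long-form table: time_s, chamber, species, concentration_ng_per_ml."""
    rows = []
    for state in trajectory:
        for chamber in range(1, state.n_chambers + 1):
            for species in state.species:
                rows.append(
                    {
                        "time_s": state.time_s,
                        "chamber": chamber,
                        "species": species,
                        "concentration_ng_per_ml": state.value(chamber, species),
                    }
                )
    return pd.DataFrame(rows)


def read_cells(path: "str | FilePath") -> pd.DataFrame:
    """Read a per-cell reporter table (array, chamber, condition, time_h,
    hes5_positive)."""
    frame = pd.read_csv(path)
    required = {"array", "chamber", "condition", "time_h", "hes5_positive"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"cell table missing columns: {sorted(missing)}")
    frame["hes5_positive"] = frame["hes5_positive"].astype(bool)
    return frame


def write_table(frame: pd.DataFrame, path: "str | FilePath") -> None:
    frame.to_csv(path, index=False)
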