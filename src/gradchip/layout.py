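"""Logical and geometric structure of the chip.

The chip is organised as ``n_arrays`` identical chamber arrays (columns).
Each array holds ``chambers_per_array`` serially connected culture chambers
fed by ``channels_per_array`` independently addressable liquid channels.
Chambers within an array are numbered 1..m from the top; a top-down pulse
(PATH1) enters at chamber 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

from .errors import ValidationError

__all__ = [
    "ChamberGeometry",
    "ChipLayout",
    "build_layout",
    "layout_summary",
    "default_geometry",
    "default_layout",
]

#: Accepted channel cross-section classes. Flow-layer channels moulded with a
#: reflowed (rounded) profile can be pinched shut by membrane valves;
#: rectangular ones cannot.
CHANNEL_HEIGHT_CLASSES = ("rounded", "rectangular")


@dataclass(frozen=True)
class ChamberGeometry:
    """Planar geometry of one culture chamber, lengths in micrometres.

    The exchange window is the sub-region of the chamber wall through which
    one feed channel exchanges liquid with the chamber; it must fit inside
    the chamber footprint.
    """

    chamber_width_um: float = 250.0
    chamber_length_um: float = 2000.0
    exchange_window_width_um: float = 250.0
    exchange_window_length_um: float = 790.0
    channel_height_class: str = "rounded"

    def __post_init__(self) -> None:
        for name in (
            "chamber_width_um",
            "chamber_length_um",
            "exchange_window_width_um",
            "exchange_window_length_um",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if self.exchange_window_length_um > self.chamber_length_um:
            raise ValidationError(
                "exchange_window_length_um must not exceed chamber_length_um "
                f"({self.exchange_window_length_um} > {self.chamber_length_um})"
            )
        if self.channel_height_class not in CHANNEL_HEIGHT_CLASSES:
            raise ValidationError(
                f"channel_height_class must be one of {CHANNEL_HEIGHT_CLASSES}, "
                f"got {self.channel_height_class!r}"
            )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ChamberGeometry":
        return cls(**dict(data))


def default_geometry() -> ChamberGeometry:
    """Chamber 250 x 2000 um with a 250 x 790 um exchange window."""
    return ChamberGeometry()


@dataclass(frozen=True)
class ChipLayout:
    """The chip as arrays x chambers x channels, plus chamber geometry.

    ``metadata`` carries inert device facts (footprint, valve closing
    pressure range); nothing in it is simulated.
    """

    n_arrays: int
    chambers_per_array: int
    channels_per_array: int
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_arrays", "chambers_per_array", "channels_per_array"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise ValidationError(f"{name} must be an integer, got {value!r}")
            if value < 1:
                raise ValidationError(f"{name} must be >= 1, got {value}")

    @property
    def n_chambers(self) -> int:
        return self.n_arrays * self.chambers_per_array

    @property
    def n_inlets(self) -> int:
        return self.n_arrays * self.channels_per_array

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_arrays": self.n_arrays,
            "chambers_per_array": self.chambers_per_array,
            "channels_per_array": self.channels_per_array,
            "geometry": self.geometry.to_dict(),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ChipLayout":
        data = dict(data)
        geometry = data.get("geometry", {})
        if isinstance(geometry, Mapping):
            geometry = ChamberGeometry.from_dict(geometry)
        return cls(
            n_arrays=data["n_arrays"],
            chambers_per_array=data["chambers_per_array"],
            channels_per_array=data["channels_per_array"],
            geometry=geometry,
            metadata=dict(data.get("metadata", {})),
        )


#: Device facts recorded for reference only.
DEFAULT_METADATA = {
    "footprint_cm": [6.0, 5.0, 0.5],
    "valve_closing_pressure_psi": [25.0, 30.0],
}


def build_layout(
    n_arrays: int,
    chambers_per_array: int,
    channels_per_array: int,
    geometry: ChamberGeometry | None = None,
    metadata: Mapping[str, Any] | None = None,
) -> ChipLayout:
    """Construct and validate a chip layout.

    Raises
    ------
    ValidationError
        If any count is < 1 (the message names the offending field) or the
        geometry is invalid.
    """
    return ChipLayout(
        n_arrays=n_arrays,
        chambers_per_array=chambers_per_array,
        channels_per_array=channels_per_array,
        geometry=geometry if geometry is not None else default_geometry(),
        metadata=dict(metadata) if metadata is not None else dict(DEFAULT_METADATA),
    )


def default_layout() -> ChipLayout:
    """The reference chip: 8 arrays x 5 chambers, 3 channels per array."""
    return build_layout(8, 5, 3)


def layout_summary(layout: ChipLayout) -> dict[str, int]:
    """Derived capacity counts: total chambers, total inlets, arrays."""
    return {
        "chambers": layout.n_chambers,
        "inlets": layout.n_inlets,
        "arrays": layout.n_arrays,
    }
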