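"""Combinatorial (k-control-1) valve multiplexer design and verification.

Each flow channel is assigned a unique k-subset of control valves.
Pressurizing a valve closes every channel whose address contains it, so a
channel flows only while none of its k address valves is pressurized.
With n valves, up to C(n, k) channels can be addressed; isolating one
channel is done by pressurizing the complement of its address.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

from .errors import ValidationError

__all__ = [
    "MuxDesign",
    "ActuationPattern",
    "IsolationResult",
    "min_valves",
    "assign_addresses",
    "actuation_pattern",
    "is_open",
    "verify_isolation",
]


@dataclass(frozen=True)
class MuxDesign:
    """A valve-multiplexer address map.

    ``addresses`` maps 1-based channel index -> frozenset of valve indices
    (each of size ``k``, valves numbered 1..n_valves).
    """

    n_valves: int
    k: int
    addresses: dict[int, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_valves < 1:
            raise ValidationError(f"n_valves must be >= 1, got {self.n_valves}")
        if not 1 <= self.k <= self.n_valves:
            raise ValidationError(f"k must be in 1..n_valves, got {self.k}")
        if len(self.addresses) > comb(self.n_valves, self.k):
            raise ValidationError(
                f"{len(self.addresses)} channels exceed C({self.n_valves},{self.k})"
                f" = {comb(self.n_valves, self.k)} available addresses"
            )
        for channel, address in self.addresses.items():
            address = frozenset(address)
            if len(address) != self.k:
                raise ValidationError(
                    f"channel {channel}: address must have exactly k={self.k} valves"
                )
            if not address <= frozenset(range(1, self.n_valves + 1)):
                raise ValidationError(
                    f"channel {channel}: address {sorted(address)} outside 1..{self.n_valves}"
                )

    def validate(self) -> None:
        """Check the pairwise-distinct address invariant.

        Kept out of ``__post_init__`` so that malformed designs can still be
        represented and diagnosed by :func:`verify_isolation`.
        """
        seen: dict[frozenset[int], int] = {}
        for channel, address in self.addresses.items():
            if address in seen:
                raise ValidationError(
                    f"channels {seen[address]} and {channel} share address "
                    f"{sorted(address)}"
                )
            seen[address] = channel

    @property
    def n_channels(self) -> int:
        return len(self.addresses)

    def address(self, channel: int) -> frozenset[int]:
        try:
            return self.addresses[channel]
        except KeyError:
            raise KeyError(f"unknown channel index {channel}") from None

    def to_dict(self) -> dict:
        return {
            "n_valves": self.n_valves,
            "k": self.k,
            "addresses": {str(c): sorted(a) for c, a in self.addresses.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MuxDesign":
        design = cls(
            n_valves=data["n_valves"],
            k=data["k"],
            addresses={int(c): frozenset(a) for c, a in data["addresses"].items()},
        )
        design.validate()
        return design


@dataclass(frozen=True)
class ActuationPattern:
    """The set of pressurized (closed) control valves."""

    pressurized: frozenset[int]

    @classmethod
    def of(cls, *valves: int) -> "ActuationPattern":
        return cls(frozenset(valves))


@dataclass(frozen=True)
class IsolationResult:
    """Outcome of an exhaustive isolation check; falsy when violations exist.

    ``violations`` lists (selected_channel, leaking_channel) pairs: channels
    left open while some other channel was selected.
    """

    ok: bool
    violations: tuple[tuple[int, int], ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def min_valves(n_channels: int, k: int) -> int:
    """Smallest valve count n >= k with C(n, k) >= n_channels."""
    if n_channels < 1:
        raise ValidationError(f"n_channels must be >= 1, got {n_channels}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    n = k
    while comb(n, k) < n_channels:
        n += 1
    return n


def assign_addresses(n_channels: int, k: int) -> MuxDesign:
    """Address ``n_channels`` channels with the minimum valve count.

    Channels 1..n_channels receive the lexicographically first k-subsets of
    {1..n_valves}; the order is deterministic so actuation schedules are
    reproducible.
    """
    n = min_valves(n_channels, k)
    subsets = combinations(range(1, n + 1), k)
    addresses = {
        channel: frozenset(subset)
        for channel, subset in zip(range(1, n_channels + 1), subsets)
    }
    return MuxDesign(n_valves=n, k=k, addresses=addresses)


def actuation_pattern(design: MuxDesign, channel: int) -> ActuationPattern:
    """Pattern isolating ``channel``: pressurize every valve not in its address."""
    address = design.address(channel)
    return ActuationPattern(frozenset(range(1, design.n_valves + 1)) - address)


def is_open(design: MuxDesign, channel: int, pattern: ActuationPattern) -> bool:
    """True iff none of the channel's address valves is pressurized."""
    return not (design.address(channel) & pattern.pressurized)


def verify_isolation(design: MuxDesign) -> IsolationResult:
    """Exhaustively check that each channel's pattern opens only that channel."""
    violations: list[tuple[int, int]] = []
    for selected in design.addresses:
        pattern = actuation_pattern(design, selected)
        for other in design.addresses:
            opened = is_open(design, other, pattern)
            if opened != (other == selected):
                violations.append((selected, other))
    return IsolationResult(ok=not violations, violations=tuple(violations))
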