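"""Data model for two-level nets-within-nets.

Markings are label multisets: black (indistinguishable) tokens use the
reserved label :data:`BLACK`, coloured tokens use their entity name.  A
place may additionally host one embedded net instance (a net token), which
is how the top-level spatial grid carries one scope net per occupied cell.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Optional

BLACK = "black"

ARC_INPUT = "in"
ARC_OUTPUT = "out"
ARC_READ = "read"
ARC_INHIBITOR = "inh"

_ARC_KINDS = (ARC_INPUT, ARC_OUTPUT, ARC_READ, ARC_INHIBITOR)


@dataclass
class Place:
    name: str
    marking: Counter = field(default_factory=Counter)
    net_token: Optional["Net"] = None

    def count(self, label: Optional[str] = None) -> int:
        """Tokens matching ``label`` (``None`` matches any coloured/black token)."""
        if label is None:
            return sum(self.marking.values())
        return self.marking[label]

    def add(self, label: str, n: int = 1) -> None:
        self.marking[label] += n

    def remove(self, label: str, n: int = 1) -> None:
        if self.marking[label] < n:
            raise ValueError(f"place {self.name!r}: cannot remove {n} x {label!r}")
        self.marking[label] -= n
        if self.marking[label] == 0:
            del self.marking[label]


@dataclass(frozen=True)
class Arc:
    """Arc between a place and a transition.

    ``weight`` is the token count consumed/produced/tested; for inhibitor
    arcs it acts as the blocking threshold.  ``label`` selects the matching
    token colour (``None`` = any).
    """

    kind: str
    place: str
    weight: int = 1
    label: Optional[str] = None

    def __post_init__(self):
        if self.kind not in _ARC_KINDS:
            raise ValueError(f"unknown arc kind {self.kind!r}")
        if self.weight < 1:
            raise ValueError("arc weight must be >= 1")


@dataclass
class Transition:
    name: str
    arcs: list[Arc] = field(default_factory=list)
    p: Optional[float] = None  # firing probability; None = simulator default
    timescale: int = 1
    channel: Optional[str] = None

    def __post_init__(self):
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ValueError("firing probability must lie in [0, 1]")
        if self.timescale < 1:
            raise ValueError("transition timescale must be >= 1")


@dataclass
class Net:
    name: str
    timescale: int = 1
    places: dict[str, Place] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)

    def add_place(self, name: str, **counts: int) -> Place:
        if name not in self.places:
            self.places[name] = Place(name)
        place = self.places[name]
        for label, n in counts.items():
            place.add(label, n)
        return place

    def add_transition(self, transition: Transition) -> Transition:
        if transition.name in self.transitions:
            raise ValueError(f"duplicate transition {transition.name!r} in net {self.name!r}")
        self.transitions[transition.name] = transition
        return transition

    def check_arcs(self) -> None:
        for transition in self.transitions.values():
            for arc in transition.arcs:
                if arc.place not in self.places:
                    raise KeyError(
                        f"dangling arc: transition {transition.name!r} references "
                        f"unknown place {arc.place!r} in net {self.name!r}"
                    )


@dataclass(frozen=True)
class Channel:
    """Synchronous interlock: all endpoint transitions fire together or not at all."""

    id: str
    endpoints: tuple[tuple[str, str], ...]  # (net name, transition name)


@dataclass(frozen=True)
class MirrorBinding:
    """Keeps the filtered coloured content of an upper and a lower place equal."""

    upper: tuple[str, str]  # (net name, place name)
    lower: tuple[str, str]
    labels: frozenset[str]


@dataclass
class NwnModel:
    """A compiled two-level model: grid net on top, scope nets as net tokens."""

    top_net: Net
    scope_nets: dict[str, Net] = field(default_factory=dict)
    bindings: list[MirrorBinding] = field(default_factory=list)
    channels: dict[str, Channel] = field(default_factory=dict)

    def nets(self) -> Iterator[Net]:
        yield self.top_net
        for name in sorted(self.scope_nets):
            yield self.scope_nets[name]

    def net(self, name: str) -> Net:
        if name == self.top_net.name:
            return self.top_net
        return self.scope_nets[name]

    def place(self, ref: tuple[str, str]) -> Place:
        net_name, place_name = ref
        return self.net(net_name).places[place_name]


def structure_signature(model: NwnModel) -> tuple:
    """Canonical structural fingerprint of a model (markings excluded).

    Two compilations of the same AST must produce equal signatures.
    """

    def net_sig(net: Net) -> tuple:
        return (
            net.name,
            net.timescale,
            tuple(sorted(net.places)),
            tuple(
                (
                    t.name,
                    t.p,
                    t.timescale,
                    t.channel,
                    tuple(sorted((a.kind, a.place, a.weight, a.label) for a in t.arcs)),
                )
                for t in sorted(net.transitions.values(), key=lambda t: t.name)
            ),
        )

    return (
        net_sig(model.top_net),
        tuple(net_sig(model.scope_nets[k]) for k in sorted(model.scope_nets)),
        tuple(sorted((b.upper, b.lower, tuple(sorted(b.labels))) for b in model.bindings)),
        tuple(sorted((c.id, c.endpoints) for c in model.channels.values())),
    )
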