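"""Abstract syntax for the design language.

The tree mirrors the textual layout: a MODULE owns SCOPEs and DIFFUSION
declarations; each SCOPE owns PROCESS instantiations, signal declarations
and an optional initial MARKING; a PROCESS owns construct statements.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class BaseType(enum.Enum):
    GENE = "GENE"
    MRNA = "MRNA"
    PROTEIN = "PROTEIN"
    COMPLEX = "COMPLEX"
    MOLECULE = "MOLECULE"


#: suffix convention used to infer an entity's base type from its name
SUFFIX_TO_BASE_TYPE = {
    "_gene": BaseType.GENE,
    "_mrna": BaseType.MRNA,
    "_protein": BaseType.PROTEIN,
    "_complex": BaseType.COMPLEX,
    "_molecule": BaseType.MOLECULE,
}


def infer_base_type(name: str) -> BaseType:
    """Infer the base type of an entity from its name suffix.

    Names without a recognized suffix default to MOLECULE.
    """
    low = name.lower()
    for suffix, base in SUFFIX_TO_BASE_TYPE.items():
        if low.endswith(suffix):
            return base
    return BaseType.MOLECULE


@dataclass(frozen=True)
class EntityRef:
    name: str
    base_type: BaseType

    @classmethod
    def from_name(cls, name: str) -> "EntityRef":
        return cls(name=name, base_type=infer_base_type(name))


class Direction(enum.Enum):
    INPUT = "input"
    OUTPUT = "output"
    MODIFIER = "modifier"


@dataclass(frozen=True)
class Term:
    """A stoichiometric participant: ``k*entity`` (k defaults to 1)."""

    entity: EntityRef
    multiplier: int = 1
    direction: Direction = Direction.INPUT


class ConstructKind(enum.Enum):
    TRANSCRIPTION = "TRANSCRIPTION"
    TRANSLATION = "TRANSLATION"
    DEGRADATION = "DEGRADATION"
    PROTEIN_COMPLEX_FORMATION = "PROTEIN_COMPLEX_FORMATION"
    ENZYMATIC_REACTION = "ENZYMATIC_REACTION"
    CUSTOM_PROCESS = "CUSTOM_PROCESS"


class Role(enum.Enum):
    INDUCERS = "INDUCERS"
    INHIBITORS = "INHIBITORS"
    ACTIVATORS = "ACTIVATORS"


@dataclass(frozen=True)
class ConstructDecl:
    kind: ConstructKind
    participants: tuple[Term, ...]
    roles: tuple[tuple[Role, Term], ...] = ()
    line: int = 0

    def inputs(self) -> tuple[Term, ...]:
        return tuple(t for t in self.participants if t.direction is Direction.INPUT)

    def outputs(self) -> tuple[Term, ...]:
        return tuple(t for t in self.participants if t.direction is Direction.OUTPUT)

    def modifiers(self) -> tuple[Term, ...]:
        return tuple(t for t in self.participants if t.direction is Direction.MODIFIER)


@dataclass
class ProcessDecl:
    id: str
    timescale: int = 1
    constructs: list[ConstructDecl] = field(default_factory=list)
    line: int = 0


@dataclass
class ProcessRef:
    """Reuse of a process declared elsewhere, by id alone."""

    id: str
    line: int = 0
    resolved: Optional[ProcessDecl] = None


class SignalKind(enum.Enum):
    PARACRINE_SIGNAL = "PARACRINE_SIGNAL"
    JUXTACRINE_SIGNAL = "JUXTACRINE_SIGNAL"


class SignalDirection(enum.Enum):
    EMIT = "emit"
    RECEIVE = "receive"


@dataclass(frozen=True)
class SignalDecl:
    kind: SignalKind
    direction: SignalDirection
    entity: EntityRef
    partner: Optional[str] = None  # scope id, juxtacrine only
    line: int = 0


@dataclass(frozen=True)
class GridCoord:
    x: int
    y: int


@dataclass
class ScopeDecl:
    id: str
    coord: GridCoord
    processes: list[ProcessDecl | ProcessRef] = field(default_factory=list)
    signals: list[SignalDecl] = field(default_factory=list)
    marking: list[Term] = field(default_factory=list)
    line: int = 0


@dataclass(frozen=True)
class DiffusionDecl:
    entity: EntityRef
    endpoints: tuple[str, str] | None  # None means grid-wide ("all")
    bidirectional: bool = True
    line: int = 0


@dataclass
class ModuleDecl:
    name: str
    timescale: int = 1
    scopes: list[ScopeDecl] = field(default_factory=list)
    diffusions: list[DiffusionDecl] = field(default_factory=list)

    def scope(self, scope_id: str) -> ScopeDecl:
        for s in self.scopes:
            if s.id == scope_id:
                return s
        raise KeyError(scope_id)

    def grid_shape(self) -> tuple[int, int]:
        """(width, height) of the smallest grid containing every scope."""
        if not self.scopes:
            return (0, 0)
        return (
            max(s.coord.x for s in self.scopes) + 1,
            max(s.coord.y for s in self.scopes) + 1,
        )
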