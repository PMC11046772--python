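"""Cross-reference validation and process-reuse resolution."""
from __future__ import annotations

import copy
from dataclasses import dataclass

from .ast import (
    BaseType,
    ConstructKind,
    ModuleDecl,
    ProcessDecl,
    ProcessRef,
    SignalKind,
)

__all__ = ["Diagnostic", "validate", "resolve_reuse", "strip_positions", "moore_adjacent"]


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    line: int
    message: str


def moore_adjacent(a, b) -> bool:
    """True iff the two grid coordinates are distinct 8-neighbourhood cells."""
    return (a.x, a.y) != (b.x, b.y) and max(abs(a.x - b.x), abs(a.y - b.y)) == 1


def _process_definitions(module: ModuleDecl) -> dict[str, list[ProcessDecl]]:
    defs: dict[str, list[ProcessDecl]] = {}
    for scope in module.scopes:
        for proc in scope.processes:
            if isinstance(proc, ProcessDecl):
                defs.setdefault(proc.id, []).append(proc)
    return defs


def validate(module: ModuleDecl) -> list[Diagnostic]:
    """Check every module-level invariant; returns diagnostics (empty iff valid)."""
    diags: list[Diagnostic] = []
    err = lambda line, msg: diags.append(Diagnostic("error", line, msg))
    warn = lambda line, msg: diags.append(Diagnostic("warning", line, msg))

    if module.timescale < 1:
        err(1, f"module timescale must be >= 1, got {module.timescale}")

    seen_ids: dict[str, int] = {}
    seen_coords: dict[tuple[int, int], str] = {}
    for scope in module.scopes:
        if scope.id in seen_ids:
            err(scope.line, f"duplicate scope id {scope.id!r}")
        seen_ids[scope.id] = scope.line
        key = (scope.coord.x, scope.coord.y)
        if key in seen_coords:
            err(scope.line, f"duplicate coordinate {key} shared by {seen_coords[key]!r} and {scope.id!r}")
        seen_coords.setdefault(key, scope.id)
        if scope.coord.x < 0 or scope.coord.y < 0:
            err(scope.line, f"scope {scope.id!r} has negative coordinate {key}")

    defs = _process_definitions(module)
    scope_by_id = {s.id: s for s in module.scopes}

    for scope in module.scopes:
        for proc in scope.processes:
            if isinstance(proc, ProcessRef):
                n = len(defs.get(proc.id, []))
                if n == 0:
                    err(proc.line, f"unresolved process {proc.id!r}")
                elif n > 1:
                    err(proc.line, f"ambiguous reuse of process {proc.id!r}: {n} definitions")
            else:
                if proc.timescale < 1:
                    err(proc.line, f"process {proc.id!r} timescale must be >= 1")
                for construct in proc.constructs:
                    diags.extend(_check_construct_types(construct))
        for signal in scope.signals:
            if signal.kind is SignalKind.JUXTACRINE_SIGNAL:
                if signal.partner is None:
                    err(signal.line, "juxtacrine signal requires a partner scope")
                elif signal.partner not in scope_by_id:
                    err(signal.line, f"juxtacrine partner {signal.partner!r} is not a declared scope")
                elif not moore_adjacent(scope.coord, scope_by_id[signal.partner].coord):
                    err(
                        signal.line,
                        f"juxtacrine partner {signal.partner!r} is not grid-adjacent to {scope.id!r}",
                    )
            elif signal.partner is not None:
                warn(signal.line, "paracrine signals take no partner; ignored")

    for diffusion in module.diffusions:
        if diffusion.endpoints is not None:
            for endpoint in diffusion.endpoints:
                if endpoint not in scope_by_id:
                    err(diffusion.line, f"diffusion endpoint {endpoint!r} is not a declared scope")

    return diags


def _check_construct_types(construct) -> list[Diagnostic]:
    diags: list[Diagnostic] = []
    expectations = {
        ConstructKind.TRANSCRIPTION: (BaseType.GENE, BaseType.MRNA),
        ConstructKind.TRANSLATION: (BaseType.MRNA, BaseType.PROTEIN),
    }
    if construct.kind in expectations:
        want_template, want_product = expectations[construct.kind]
        template = construct.modifiers()[0]
        product = construct.outputs()[0]
        if template.entity.base_type is not want_template:
            diags.append(Diagnostic(
                "error", construct.line,
                f"{construct.kind.value} template {template.entity.name!r} is not a {want_template.value}",
            ))
        if product.entity.base_type is not want_product:
            diags.append(Diagnostic(
                "error", construct.line,
                f"{construct.kind.value} product {product.entity.name!r} is not a {want_product.value}",
            ))
    return diags


def resolve_reuse(module: ModuleDecl) -> ModuleDecl:
    """Link every :class:`ProcessRef` to its unique defining :class:`ProcessDecl`.

    Definition order is preserved so the compiler can number instances in
    source order.  Raises ``ValueError`` on dangling or ambiguous references.
    """
    defs = _process_definitions(module)
    for scope in module.scopes:
        for proc in scope.processes:
            if isinstance(proc, ProcessRef):
                candidates = defs.get(proc.id, [])
                if not candidates:
                    raise ValueError(f"unresolved process {proc.id!r}")
                if len(candidates) > 1:
                    raise ValueError(f"ambiguous reuse of process {proc.id!r}")
                proc.resolved = candidates[0]
    return module


def strip_positions(module: ModuleDecl) -> ModuleDecl:
    """Copy of the AST with all source-line fields zeroed (for equality tests)."""
    clone = copy.deepcopy(module)
    for scope in clone.scopes:
        scope.line = 0
        for i, proc in enumerate(scope.processes):
            if isinstance(proc, ProcessRef):
                scope.processes[i] = ProcessRef(id=proc.id, line=0, resolved=None)
            else:
                proc.line = 0
                proc.constructs = [
                    type(c)(kind=c.kind, participants=c.participants, roles=c.roles, line=0)
                    for c in proc.constructs
                ]
        scope.signals = [
            type(s)(kind=s.kind, direction=s.direction, entity=s.entity, partner=s.partner, line=0)
            for s in scope.signals
        ]
    clone.diffusions = [
        type(d)(entity=d.entity, endpoints=d.endpoints, bidirectional=d.bidirectional, line=0)
        for d in clone.diffusions
    ]
    return clone
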