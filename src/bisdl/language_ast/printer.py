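"""Canonical pretty-printer: ``parse(pretty_print(parse(s)))`` equals ``parse(s)``."""
from __future__ import annotations

from .ast import (
    ConstructDecl,
    ConstructKind,
    DiffusionDecl,
    ModuleDecl,
    ProcessDecl,
    ProcessRef,
    ScopeDecl,
    SignalDecl,
    SignalKind,
    Term,
)

_INDENT = "    "


def _term(t: Term) -> str:
    return t.entity.name if t.multiplier == 1 else f"{t.multiplier}*{t.entity.name}"


def _terms(terms, sep: str = " + ") -> str:
    return sep.join(_term(t) for t in terms)


def _construct(c: ConstructDecl) -> str:
    roles = "".join(f", {role.value}({_term(term)})" for role, term in c.roles)
    if c.kind in (ConstructKind.TRANSCRIPTION, ConstructKind.TRANSLATION):
        template = c.modifiers()[0]
        product = c.outputs()[0]
        args = f"{_term(template)}, {_term(product)}"
    elif c.kind is ConstructKind.DEGRADATION:
        args = _term(c.inputs()[0])
    elif c.kind is ConstructKind.PROTEIN_COMPLEX_FORMATION:
        args = _terms(list(c.inputs()) + list(c.outputs()), sep=", ")
    elif c.kind is ConstructKind.ENZYMATIC_REACTION:
        enzyme = c.modifiers()[0]
        args = f"{_term(enzyme)}, {_terms(c.inputs())} -> {_terms(c.outputs())}"
    else:  # CUSTOM_PROCESS
        args = f"{_terms(c.inputs())} -> {_terms(c.outputs())}"
    return f"{c.kind.value}({args}{roles})"


def _signal(s: SignalDecl) -> str:
    if s.kind is SignalKind.JUXTACRINE_SIGNAL:
        return f"{s.kind.value}({s.direction.value}, {s.entity.name}, {s.partner})"
    return f"{s.kind.value}({s.direction.value}, {s.entity.name})"


def _diffusion(d: DiffusionDecl) -> str:
    if d.endpoints is None:
        ep = "all"
    else:
        sep = "<->" if d.bidirectional else "->"
        ep = f"{d.endpoints[0]} {sep} {d.endpoints[1]}"
    return f"DIFFUSION({d.entity.name}, {ep})"


def _scope(scope: ScopeDecl, out: list[str]) -> None:
    out.append(f"{_INDENT}SCOPE {scope.id}({scope.coord.x}, {scope.coord.y})")
    if scope.marking:
        out.append(f"{_INDENT * 2}MARKING({_terms(scope.marking, sep=', ')})")
    for proc in scope.processes:
        if isinstance(proc, ProcessRef):
            out.append(f"{_INDENT * 2}PROCESS {proc.id}")
            continue
        assert isinstance(proc, ProcessDecl)
        out.append(f"{_INDENT * 2}PROCESS {proc.id}")
        out.append(f"{_INDENT * 3}TIMESCALE {proc.timescale}")
        for construct in proc.constructs:
            out.append(f"{_INDENT * 3}{_construct(construct)}")
    for signal in scope.signals:
        out.append(f"{_INDENT * 2}{_signal(signal)}")


def pretty_print(module: ModuleDecl) -> str:
    """Render a module back to canonical source text."""
    out = [f"MODULE {module.name}", f"{_INDENT}TIMESCALE {module.timescale}"]
    for scope in module.scopes:
        _scope(scope, out)
    for diffusion in module.diffusions:
        out.append(f"{_INDENT}{_diffusion(diffusion)}")
    return "\n".join(out) + "\n"
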