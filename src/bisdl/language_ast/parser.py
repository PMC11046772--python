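"""Hand-written parser for the indentation-delimited source syntax.

The surface syntax is keyword-led: each line starts with an upper-case
keyword (MODULE, TIMESCALE, SCOPE, PROCESS, MARKING, DIFFUSION, a signal
keyword or a construct keyword).  Blocks are delimited by indentation,
arguments are comma-separated inside parentheses, ``k*name`` expresses
stoichiometric multipliers and ``#`` starts a comment.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .ast import (
    ConstructDecl,
    ConstructKind,
    DiffusionDecl,
    Direction,
    EntityRef,
    GridCoord,
    ModuleDecl,
    ProcessDecl,
    ProcessRef,
    Role,
    ScopeDecl,
    SignalDecl,
    SignalDirection,
    SignalKind,
    Term,
)

__all__ = ["parse", "ParseError"]


class ParseError(ValueError):
    """Syntax error carrying 1-based line and column numbers."""

    def __init__(self, message: str, line: int, col: int = 1):
        super().__init__(f"line {line}, col {col}: {message}")
        self.line = line
        self.col = col


@dataclass
class _Line:
    indent: int
    text: str
    lineno: int


_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"
_RE_MODULE = re.compile(rf"^MODULE\s+({_IDENT})$")
_RE_TIMESCALE = re.compile(r"^TIMESCALE\s+(\d+)$")
_RE_SCOPE = re.compile(rf"^SCOPE\s+({_IDENT})\s*\(\s*(-?\d+)\s*,\s*(-?\d+)\s*\)$")
_RE_PROCESS = re.compile(rf"^PROCESS\s+({_IDENT})$")
_RE_CALL = re.compile(rf"^({_IDENT})\s*\((.*)\)$")
_RE_TERM = re.compile(rf"^(?:(\d+)\s*\*\s*)?({_IDENT})$")

_CONSTRUCT_KINDS = {k.value for k in ConstructKind}
_ROLE_NAMES = {r.value for r in Role}
_SIGNAL_KINDS = {k.value for k in SignalKind}


def _tokenize(source_text: str) -> list[_Line]:
    lines: list[_Line] = []
    for lineno, raw in enumerate(source_text.splitlines(), start=1):
        text = raw.split("#", 1)[0].rstrip()
        if not text.strip():
            continue
        stripped = text.lstrip(" ")
        indent = len(text) - len(stripped)
        if "\t" in text[: indent + 1]:
            raise ParseError("tab characters are not allowed in indentation", lineno)
        lines.append(_Line(indent, stripped, lineno))
    return lines


def _split_top_commas(s: str, lineno: int) -> list[str]:
    """Split on commas not nested inside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError("unbalanced parentheses", lineno)
        if ch == "," and depth == 0:
            parts.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise ParseError("unbalanced parentheses", lineno)
    last = "".join(cur).strip()
    if last or parts:
        parts.append(last)
    return [p for p in parts if p != ""]


def _parse_term(text: str, lineno: int, direction: Direction) -> Term:
    m = _RE_TERM.match(text.strip())
    if not m:
        raise ParseError(f"malformed term {text!r}", lineno)
    mult = int(m.group(1)) if m.group(1) else 1
    if mult < 1:
        raise ParseError(f"multiplier must be >= 1 in {text!r}", lineno)
    return Term(entity=EntityRef.from_name(m.group(2)), multiplier=mult, direction=direction)


def _parse_term_group(text: str, lineno: int, direction: Direction) -> list[Term]:
    """Parse ``a + 2*b`` into terms sharing one direction."""
    return [_parse_term(p, lineno, direction) for p in text.split("+") if p.strip()]


def _parse_arrow(text: str, lineno: int) -> tuple[list[Term], list[Term]]:
    if "->" not in text:
        raise ParseError(f"expected 'inputs -> outputs' in {text!r}", lineno)
    left, right = text.split("->", 1)
    ins = _parse_term_group(left, lineno, Direction.INPUT) if left.strip() else []
    outs = _parse_term_group(right, lineno, Direction.OUTPUT) if right.strip() else []
    return ins, outs


def _parse_construct(kind_name: str, argtext: str, lineno: int) -> ConstructDecl:
    kind = ConstructKind(kind_name)
    args = _split_top_commas(argtext, lineno)

    roles: list[tuple[Role, Term]] = []
    positional: list[str] = []
    for arg in args:
        call = _RE_CALL.match(arg)
        if call and call.group(1) in _ROLE_NAMES:
            role = Role(call.group(1))
            for part in _split_top_commas(call.group(2), lineno):
                roles.append((role, _parse_term(part, lineno, Direction.MODIFIER)))
        else:
            positional.append(arg)

    participants: list[Term] = []
    if kind in (ConstructKind.TRANSCRIPTION, ConstructKind.TRANSLATION):
        if len(positional) != 2:
            raise ParseError(f"{kind.value} expects (template, product)", lineno)
        participants.append(_parse_term(positional[0], lineno, Direction.MODIFIER))
        participants.append(_parse_term(positional[1], lineno, Direction.OUTPUT))
    elif kind is ConstructKind.DEGRADATION:
        if len(positional) != 1:
            raise ParseError("DEGRADATION expects a single term", lineno)
        participants.append(_parse_term(positional[0], lineno, Direction.INPUT))
    elif kind is ConstructKind.PROTEIN_COMPLEX_FORMATION:
        if len(positional) < 2:
            raise ParseError(
                "PROTEIN_COMPLEX_FORMATION expects components and a product", lineno
            )
        for part in positional[:-1]:
            participants.extend(_parse_term_group(part, lineno, Direction.INPUT))
        participants.append(_parse_term(positional[-1], lineno, Direction.OUTPUT))
    elif kind is ConstructKind.ENZYMATIC_REACTION:
        if len(positional) != 2:
            raise ParseError(
                "ENZYMATIC_REACTION expects (enzyme, substrates -> products)", lineno
            )
        participants.append(_parse_term(positional[0], lineno, Direction.MODIFIER))
        ins, outs = _parse_arrow(positional[1], lineno)
        participants.extend(ins)
        participants.extend(outs)
    elif kind is ConstructKind.CUSTOM_PROCESS:
        if len(positional) != 1:
            raise ParseError("CUSTOM_PROCESS expects 'inputs -> outputs'", lineno)
        ins, outs = _parse_arrow(positional[0], lineno)
        participants.extend(ins)
        participants.extend(outs)

    return ConstructDecl(
        kind=kind, participants=tuple(participants), roles=tuple(roles), line=lineno
    )


def _parse_signal(kind_name: str, argtext: str, lineno: int) -> SignalDecl:
    kind = SignalKind(kind_name)
    args = _split_top_commas(argtext, lineno)
    if kind is SignalKind.PARACRINE_SIGNAL and len(args) != 2:
        raise ParseError("PARACRINE_SIGNAL expects (emit|receive, entity)", lineno)
    if kind is SignalKind.JUXTACRINE_SIGNAL and len(args) != 3:
        raise ParseError(
            "JUXTACRINE_SIGNAL expects (emit|receive, entity, partner_scope)", lineno
        )
    try:
        direction = SignalDirection(args[0].lower())
    except ValueError:
        raise ParseError(f"signal direction must be emit or receive, got {args[0]!r}", lineno)
    entity = EntityRef.from_name(args[1])
    partner = args[2] if len(args) == 3 else None
    return SignalDecl(kind=kind, direction=direction, entity=entity, partner=partner, line=lineno)


def _parse_diffusion(argtext: str, lineno: int) -> DiffusionDecl:
    args = _split_top_commas(argtext, lineno)
    if len(args) != 2:
        raise ParseError("DIFFUSION expects (entity, endpoints)", lineno)
    entity = EntityRef.from_name(args[0])
    ep = args[1]
    if ep == "all":
        return DiffusionDecl(entity=entity, endpoints=None, bidirectional=True, line=lineno)
    for sep, bidi in (("<->", True), ("->", False)):
        if sep in ep:
            a, b = (p.strip() for p in ep.split(sep, 1))
            if not a or not b:
                raise ParseError(f"malformed diffusion endpoints {ep!r}", lineno)
            return DiffusionDecl(entity=entity, endpoints=(a, b), bidirectional=bidi, line=lineno)
    raise ParseError(
        f"diffusion endpoints must be 'a <-> b', 'a -> b' or 'all', got {ep!r}", lineno
    )


class _Parser:
    def __init__(self, lines: list[_Line]):
        self.lines = lines
        self.pos = 0

    def peek(self) -> _Line | None:
        return self.lines[self.pos] if self.pos < len(self.lines) else None

    def next(self) -> _Line:
        line = self.lines[self.pos]
        self.pos += 1
        return line

    def parse_module(self) -> ModuleDecl:
        head = self.peek()
        if head is None:
            raise ParseError("empty source", 1)
        m = _RE_MODULE.match(head.text)
        if not m:
            raise ParseError(f"expected 'MODULE <name>', got {head.text!r}", head.lineno)
        self.next()
        module = ModuleDecl(name=m.group(1))
        saw_timescale = False
        while (line := self.peek()) is not None:
            if line.indent <= head.indent:
                raise ParseError(
                    f"unexpected top-level line {line.text!r}", line.lineno
                )
            if ts := _RE_TIMESCALE.match(line.text):
                if saw_timescale:
                    raise ParseError("duplicate module TIMESCALE", line.lineno)
                module.timescale = self._positive(ts.group(1), line.lineno)
                saw_timescale = True
                self.next()
            elif _RE_SCOPE.match(line.text):
                module.scopes.append(self.parse_scope())
            elif call := _RE_CALL.match(line.text):
                if call.group(1) != "DIFFUSION":
                    raise ParseError(
                        f"unexpected keyword {call.group(1)!r} in MODULE body", line.lineno
                    )
                module.diffusions.append(_parse_diffusion(call.group(2), line.lineno))
                self.next()
            else:
                raise ParseError(f"cannot parse {line.text!r}", line.lineno)
        return module

    def _positive(self, text: str, lineno: int) -> int:
        value = int(text)
        if value < 1:
            raise ParseError(f"TIMESCALE must be >= 1, got {value}", lineno)
        return value

    def parse_scope(self) -> ScopeDecl:
        head = self.next()
        m = _RE_SCOPE.match(head.text)
        assert m is not None
        scope = ScopeDecl(
            id=m.group(1),
            coord=GridCoord(int(m.group(2)), int(m.group(3))),
            line=head.lineno,
        )
        while (line := self.peek()) is not None and line.indent > head.indent:
            if _RE_PROCESS.match(line.text):
                scope.processes.append(self.parse_process(head.indent))
                continue
            call = _RE_CALL.match(line.text)
            if call and call.group(1) in _SIGNAL_KINDS:
                scope.signals.append(_parse_signal(call.group(1), call.group(2), line.lineno))
            elif call and call.group(1) == "MARKING":
                for part in _split_top_commas(call.group(2), line.lineno):
                    scope.marking.append(_parse_term(part, line.lineno, Direction.OUTPUT))
            else:
                raise ParseError(f"cannot parse {line.text!r} in SCOPE body", line.lineno)
            self.next()
        return scope

    def parse_process(self, scope_indent: int) -> ProcessDecl | ProcessRef:
        head = self.next()
        m = _RE_PROCESS.match(head.text)
        assert m is not None
        body: list[_Line] = []
        while (line := self.peek()) is not None and line.indent > head.indent:
            body.append(self.next())
        if not body:
            return ProcessRef(id=m.group(1), line=head.lineno)
        proc = ProcessDecl(id=m.group(1), line=head.lineno)
        saw_timescale = False
        for line in body:
            if ts := _RE_TIMESCALE.match(line.text):
                if saw_timescale:
                    raise ParseError("duplicate PROCESS TIMESCALE", line.lineno)
                proc.timescale = self._positive(ts.group(1), line.lineno)
                saw_timescale = True
                continue
            call = _RE_CALL.match(line.text)
            if not call:
                raise ParseError(f"cannot parse {line.text!r} in PROCESS body", line.lineno)
            if call.group(1) not in _CONSTRUCT_KINDS:
                raise ParseError(f"unknown construct keyword {call.group(1)!r}", line.lineno)
            proc.constructs.append(_parse_construct(call.group(1), call.group(2), line.lineno))
        return proc


def parse(source_text: str) -> ModuleDecl:
    """Parse source text into a :class:`ModuleDecl`.

    Raises :class:`ParseError` (with line information) on malformed input.
    """
    if not source_text or not source_text.strip():
        raise ParseError("empty source", 1)
    return _Parser(_tokenize(source_text)).parse_module()
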