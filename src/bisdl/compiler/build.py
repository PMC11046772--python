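"""Lowering of a validated module onto a two-level nets-within-nets model.

The top net is the spatial grid: one place per SCOPE (hosting the scope
net as a net token) plus the inter-scope diffusion transitions.  Each
scope net carries the construct fragments of its process instances.
Diffusible entities are mirrored between a grid place and the entity
place of the hosted scope net, so both levels see the same marking.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from ..language_ast import (
    DiffusionDecl,
    ModuleDecl,
    ProcessDecl,
    ProcessRef,
    ScopeDecl,
    SignalDecl,
    SignalDirection,
    SignalKind,
    moore_adjacent,
    resolve_reuse,
    validate,
)
from ..nwn_core import (
    ARC_INPUT,
    ARC_OUTPUT,
    Arc,
    Channel,
    MirrorBinding,
    Net,
    NwnModel,
    Transition,
)
from .templates import expand_construct

logger = logging.getLogger(__name__)

__all__ = ["CompileError", "CompiledModel", "assign_instance_names", "compile_module"]


class CompileError(ValueError):
    def __init__(self, diagnostics):
        self.diagnostics = diagnostics
        listing = "; ".join(f"line {d.line}: {d.message}" for d in diagnostics)
        super().__init__(f"module does not validate: {listing}")


@dataclass
class CompiledModel(NwnModel):
    """An :class:`NwnModel` plus the compiler's bookkeeping."""

    module_name: str = ""
    name_registry: dict[str, str] = field(default_factory=dict)
    coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    def scope_place(self, scope_id: str):
        return self.top_net.places[scope_id]


def assign_instance_names(module: ModuleDecl) -> dict[str, str]:
    """Progressive instance names, ``<process_id>_process_<i>`` from 0 in source order.

    Keys are ``"<scope_id>:<slot>"`` where slot is the position of the
    instantiation inside its scope.
    """
    counters: dict[str, int] = {}
    registry: dict[str, str] = {}
    for scope in module.scopes:
        for slot, proc in enumerate(scope.processes):
            pid = proc.id
            i = counters.get(pid, 0)
            counters[pid] = i + 1
            registry[f"{scope.id}:{slot}"] = f"{pid}_process_{i}"
    return registry


def _resolved(proc: ProcessDecl | ProcessRef) -> ProcessDecl:
    if isinstance(proc, ProcessDecl):
        return proc
    if proc.resolved is None:
        raise ValueError(f"process reference {proc.id!r} was not resolved")
    return proc.resolved


def _unique_name(net: Net, base: str) -> str:
    if base not in net.transitions:
        return base
    i = 1
    while f"{base}_{i}" in net.transitions:
        i += 1
    return f"{base}_{i}"


def _build_scope_net(
    module: ModuleDecl, scope: ScopeDecl, registry: dict[str, str]
) -> Net:
    net = Net(name=scope.id, timescale=module.timescale)
    for slot, proc in enumerate(scope.processes):
        decl = _resolved(proc)
        prefix = registry[f"{scope.id}:{slot}"]
        effective_ts = module.timescale * decl.timescale
        for construct in decl.constructs:
            fragment = expand_construct(construct, prefix, timescale=effective_ts)
            for place in fragment.places:
                net.add_place(place)
            for transition in fragment.transitions:
                transition.name = _unique_name(net, transition.name)
                net.add_transition(transition)
    for term in scope.marking:
        net.add_place(term.entity.name, **{term.entity.name: term.multiplier})
    net.check_arcs()
    return net


def _diffusion_entities(module: ModuleDecl, scope_id: str) -> set[str]:
    """Entities whose tokens cross the grid boundary of this scope."""
    names: set[str] = set()
    for diffusion in module.diffusions:
        if diffusion.endpoints is None or scope_id in diffusion.endpoints:
            names.add(diffusion.entity.name)
    for scope in module.scopes:
        if scope.id != scope_id:
            continue
        for signal in scope.signals:
            if signal.kind is SignalKind.PARACRINE_SIGNAL:
                names.add(signal.entity.name)
    return names


def _add_top_move(top: Net, entity: str, src: str, dst: str, timescale: int) -> None:
    name = f"diff_{entity}_{src}_to_{dst}"
    if name in top.transitions:
        return
    top.add_transition(
        Transition(
            name=name,
            arcs=[
                Arc(kind=ARC_INPUT, place=src, weight=1, label=entity),
                Arc(kind=ARC_OUTPUT, place=dst, weight=1, label=entity),
            ],
            timescale=timescale,
        )
    )


def wire_diffusion(module: ModuleDecl, model: CompiledModel) -> None:
    """One top-level token-moving transition per diffusion direction."""
    top = model.top_net
    for diffusion in module.diffusions:
        entity = diffusion.entity.name
        if diffusion.endpoints is None:
            for a, b in combinations(module.scopes, 2):
                if moore_adjacent(a.coord, b.coord):
                    _add_top_move(top, entity, a.id, b.id, module.timescale)
                    _add_top_move(top, entity, b.id, a.id, module.timescale)
        else:
            a, b = diffusion.endpoints
            _add_top_move(top, entity, a, b, module.timescale)
            if diffusion.bidirectional:
                _add_top_move(top, entity, b, a, module.timescale)


def _wire_paracrine(module: ModuleDecl, model: CompiledModel) -> None:
    top = model.top_net
    for scope in module.scopes:
        for signal in scope.signals:
            if signal.kind is not SignalKind.PARACRINE_SIGNAL:
                continue
            neighbors = [
                other for other in module.scopes if moore_adjacent(scope.coord, other.coord)
            ]
            for other in neighbors:
                if signal.direction is SignalDirection.EMIT:
                    _add_top_move(top, signal.entity.name, scope.id, other.id, module.timescale)
                else:
                    _add_top_move(top, signal.entity.name, other.id, scope.id, module.timescale)


def wire_juxtacrine(module: ModuleDecl, model: CompiledModel) -> None:
    """Pair emit/receive declarations into synchronous channels (payload: 1 token)."""
    declarations: list[tuple[ScopeDecl, SignalDecl]] = [
        (scope, signal)
        for scope in module.scopes
        for signal in scope.signals
        if signal.kind is SignalKind.JUXTACRINE_SIGNAL
    ]
    receives = {
        (scope.id, signal.entity.name, signal.partner): signal
        for scope, signal in declarations
        if signal.direction is SignalDirection.RECEIVE
    }
    for scope, signal in declarations:
        if signal.direction is not SignalDirection.EMIT:
            continue
        partner = signal.partner
        entity = signal.entity.name
        if (partner, entity, scope.id) not in receives:
            logger.warning(
                "juxtacrine emit of %r from %r has no matching receive in %r; channel omitted",
                entity, scope.id, partner,
            )
            continue
        channel_id = f"jux_{entity}_{scope.id}_to_{partner}"
        emitter_net = model.scope_nets[scope.id]
        receiver_net = model.scope_nets[partner]
        emitter_net.add_place(entity)
        receiver_net.add_place(entity)
        emit_name = _unique_name(emitter_net, f"jux_emit_{entity}_to_{partner}")
        emitter_net.add_transition(
            Transition(
                name=emit_name,
                arcs=[Arc(kind=ARC_INPUT, place=entity, weight=1, label=entity)],
                timescale=module.timescale,
                channel=channel_id,
            )
        )
        receive_name = _unique_name(receiver_net, f"jux_receive_{entity}_from_{scope.id}")
        receiver_net.add_transition(
            Transition(
                name=receive_name,
                arcs=[Arc(kind=ARC_OUTPUT, place=entity, weight=1, label=entity)],
                timescale=module.timescale,
                channel=channel_id,
            )
        )
        model.channels[channel_id] = Channel(
            id=channel_id,
            endpoints=((scope.id, emit_name), (partner, receive_name)),
        )


def compile_module(module: ModuleDecl) -> CompiledModel:
    """Validate, resolve reuse and lower the module. Deterministic and pure."""
    errors = [d for d in validate(module) if d.severity == "error"]
    if errors:
        raise CompileError(errors)
    resolve_reuse(module)
    registry = assign_instance_names(module)

    top = Net(name=f"{module.name}_grid", timescale=module.timescale)
    model = CompiledModel(
        top_net=top, module_name=module.name, name_registry=registry
    )
    for scope in module.scopes:
        scope_net = _build_scope_net(module, scope, registry)
        model.scope_nets[scope.id] = scope_net
        place = top.add_place(scope.id)
        place.net_token = scope_net
        model.coords[scope.id] = (scope.coord.x, scope.coord.y)

    wire_diffusion(module, model)
    _wire_paracrine(module, model)
    wire_juxtacrine(module, model)

    # mirror each diffusible entity between the grid place and the hosted net
    for scope in module.scopes:
        scope_net = model.scope_nets[scope.id]
        for entity in sorted(_diffusion_entities(module, scope.id)):
            scope_net.add_place(entity)
            model.bindings.append(
                MirrorBinding(
                    upper=(top.name, scope.id),
                    lower=(scope.id, entity),
                    labels=frozenset({entity}),
                )
            )
            # seed the upper copy with any initial lower marking
            upper = top.places[scope.id]
            lower = scope_net.places[entity]
            have = upper.count(entity)
            want = lower.count(entity)
            if have < want:
                upper.add(entity, want - have)

    top.check_arcs()
    return model
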