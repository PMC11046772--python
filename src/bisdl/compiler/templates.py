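"""Per-construct lowering templates.

Each construct expands to a :class:`NetFragment`: one transition plus the
entity places it touches.  Fragments for the same entity within one scope
are stitched by place name, so a scope net ends up with exactly one place
per distinct entity.  Template summary:

* TRANSCRIPTION / TRANSLATION — template (gene/mRNA) on a read arc, the
  product on an output arc: templates are never consumed.
* DEGRADATION — consume the term, no outputs (sink).
* PROTEIN_COMPLEX_FORMATION — consume every component, produce the product.
* ENZYMATIC_REACTION — enzyme on a read arc; substrates consumed, products
  produced per their multipliers.
* CUSTOM_PROCESS — literal inputs -> outputs.
* roles: INDUCERS/ACTIVATORS become read arcs, INHIBITORS inhibitor arcs
  (threshold = multiplier), on any construct kind.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ..language_ast import ConstructDecl, ConstructKind, Role, Term
from ..nwn_core import (
    ARC_INHIBITOR,
    ARC_INPUT,
    ARC_OUTPUT,
    ARC_READ,
    Arc,
    Transition,
)


@dataclass
class NetFragment:
    places: set[str] = field(default_factory=set)
    transitions: list[Transition] = field(default_factory=list)


def _arc(kind: str, term: Term) -> Arc:
    return Arc(kind=kind, place=term.entity.name, weight=term.multiplier, label=term.entity.name)


_KIND_TAG = {
    ConstructKind.TRANSCRIPTION: "transcription",
    ConstructKind.TRANSLATION: "translation",
    ConstructKind.DEGRADATION: "degradation",
    ConstructKind.PROTEIN_COMPLEX_FORMATION: "complex_formation",
    ConstructKind.ENZYMATIC_REACTION: "enzymatic",
    ConstructKind.CUSTOM_PROCESS: "custom",
}


def transition_basename(construct: ConstructDecl) -> str:
    """Interpretable name stem embedding the product (or consumed) entity."""
    tag = _KIND_TAG[construct.kind]
    outputs = construct.outputs()
    if outputs:
        return f"{tag}_{outputs[0].entity.name}"
    inputs = construct.inputs()
    if inputs:
        return f"{tag}_{inputs[0].entity.name}"
    return tag


def expand_construct(
    construct: ConstructDecl, instance_prefix: str, timescale: int = 1
) -> NetFragment:
    """Expand one construct into its net fragment.

    ``instance_prefix`` is the progressive process-instance name the
    generated transition names are nested under.
    """
    fragment = NetFragment()
    arcs: list[Arc] = []
    for term in construct.modifiers():
        arcs.append(_arc(ARC_READ, term))
    for term in construct.inputs():
        arcs.append(_arc(ARC_INPUT, term))
    for term in construct.outputs():
        arcs.append(_arc(ARC_OUTPUT, term))
    for role, term in construct.roles:
        kind = ARC_INHIBITOR if role is Role.INHIBITORS else ARC_READ
        arcs.append(_arc(kind, term))
    fragment.places.update(arc.place for arc in arcs)
    name = f"{instance_prefix}_{transition_basename(construct)}"
    fragment.transitions.append(Transition(name=name, arcs=arcs, timescale=timescale))
    return fragment
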