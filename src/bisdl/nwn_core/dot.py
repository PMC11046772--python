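"""DOT (Graphviz) serialization: places as circles, transitions as boxes."""
from __future__ import annotations

from .net import ARC_INHIBITOR, ARC_INPUT, ARC_OUTPUT, ARC_READ, Net

_ARC_STYLE = {
    ARC_INPUT: "",
    ARC_OUTPUT: "",
    ARC_READ: ' style=dashed arrowhead="none" arrowtail="none"',
    ARC_INHIBITOR: ' arrowhead="odot"',
}


def _quote(name: str) -> str:
    return '"' + name.replace('"', r"\"") + '"'


def net_to_dot(net: Net) -> str:
    """Render a net as a DOT digraph (net-token places annotated)."""
    lines = [f"digraph {_quote(net.name)} {{", "  rankdir=LR;"]
    for place in sorted(net.places.values(), key=lambda p: p.name):
        tokens = sum(place.marking.values())
        label = place.name if tokens == 0 else f"{place.name}\\n{tokens} tok"
        if place.net_token is not None:
            label += f"\\n[net token: {place.net_token.name}]"
        lines.append(
            f"  {_quote('p_' + place.name)} [shape=circle label={_quote(label)}];"
        )
    for transition in sorted(net.transitions.values(), key=lambda t: t.name):
        lines.append(
            f"  {_quote('t_' + transition.name)} [shape=box label={_quote(transition.name)}];"
        )
        for arc in transition.arcs:
            p, t = _quote("p_" + arc.place), _quote("t_" + transition.name)
            attrs = f'label="{arc.weight if arc.label is None else f"{arc.weight}:{arc.label}"}"'
            attrs += _ARC_STYLE[arc.kind]
            if arc.kind == ARC_OUTPUT:
                lines.append(f"  {t} -> {p} [{attrs}];")
            else:
                lines.append(f"  {p} -> {t} [{attrs}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
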