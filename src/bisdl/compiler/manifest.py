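"""JSON manifest of a compiled model (stable key order for golden files)."""
from __future__ import annotations

import json

from ..nwn_core import Net
from .build import CompiledModel


def _net_manifest(net: Net) -> dict:
    return {
        "name": net.name,
        "timescale": net.timescale,
        "places": {
            name: {
                "marking": dict(sorted(place.marking.items())),
                "net_token": place.net_token.name if place.net_token else None,
            }
            for name, place in sorted(net.places.items())
        },
        "transitions": [
            {
                "name": t.name,
                "p": t.p,
                "timescale": t.timescale,
                "channel": t.channel,
                "arcs": sorted(
                    (
                        {"kind": a.kind, "place": a.place, "weight": a.weight, "label": a.label}
                        for a in t.arcs
                    ),
                    key=lambda a: (a["kind"], a["place"], a["label"] or ""),
                ),
            }
            for _, t in sorted(net.transitions.items())
        ],
    }


def model_manifest(model: CompiledModel) -> dict:
    return {
        "module": model.module_name,
        "coords": {k: list(v) for k, v in sorted(model.coords.items())},
        "top_net": _net_manifest(model.top_net),
        "scope_nets": {
            name: _net_manifest(net) for name, net in sorted(model.scope_nets.items())
        },
        "bindings": [
            {
                "upper": list(b.upper),
                "lower": list(b.lower),
                "labels": sorted(b.labels),
            }
            for b in sorted(model.bindings, key=lambda b: (b.upper, b.lower))
        ],
        "channels": {
            cid: [list(e) for e in ch.endpoints]
            for cid, ch in sorted(model.channels.items())
        },
        "name_registry": dict(sorted(model.name_registry.items())),
    }


def manifest_json(model: CompiledModel) -> str:
    return json.dumps(model_manifest(model), indent=2, sort_keys=True) + "\n"
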