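"""Transition enabling, stochastic firing, channels, mirroring and the tick step.

Execution semantics per tick:

* a transition with effective timescale ``T`` is visited only when
  ``tick % T == 0`` (its net's timescale is the default);
* visited transitions are swept in a freshly shuffled order, one firing
  attempt each, succeeding with probability ``p`` (default 0.6);
* channel-bound transitions fire as a rendezvous: every endpoint must be
  due and enabled, then all endpoints fire atomically;
* mirror bindings are re-satisfied after every net's sweep, so each net
  always observes the other level's latest marking.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .net import (
    ARC_INHIBITOR,
    ARC_INPUT,
    ARC_OUTPUT,
    ARC_READ,
    BLACK,
    Channel,
    MirrorBinding,
    Net,
    NwnModel,
    Transition,
)
from .rng import SeededStreams

logger = logging.getLogger(__name__)

DEFAULT_FIRING_PROBABILITY = 0.6

#: (net, transition-or-channel, tick) firing event
FireEvent = tuple[str, str, int]


def enabled(transition: Transition, net: Net) -> bool:
    """Local enabling: input/read arcs covered, inhibitor arcs below threshold."""
    for arc in transition.arcs:
        if arc.place not in net.places:
            raise KeyError(
                f"dangling arc: {transition.name!r} -> unknown place {arc.place!r}"
            )
        count = net.places[arc.place].count(arc.label)
        if arc.kind in (ARC_INPUT, ARC_READ) and count < arc.weight:
            return False
        if arc.kind == ARC_INHIBITOR and count >= arc.weight:
            return False
    return True


def _consume(place, label: Optional[str], weight: int, rng: Optional[np.random.Generator]):
    """Remove ``weight`` matching tokens; random uniform choice when label is open."""
    removed: list[str] = []
    if label is not None:
        place.remove(label, weight)
        return [(label, weight)]
    for _ in range(weight):
        labels = sorted(l for l, n in place.marking.items() if n > 0)
        if not labels:
            raise ValueError(f"place {place.name!r} exhausted during firing")
        weights = np.array([place.marking[l] for l in labels], dtype=float)
        if rng is None:
            pick = labels[0]
        else:
            pick = labels[rng.choice(len(labels), p=weights / weights.sum())]
        place.remove(pick, 1)
        removed.append(pick)
    counted: dict[str, int] = {}
    for l in removed:
        counted[l] = counted.get(l, 0) + 1
    return list(counted.items())


def fire(
    transition: Transition, net: Net, rng: Optional[np.random.Generator] = None
) -> dict[tuple[str, str], int]:
    """Fire an enabled transition; returns the marking delta ``{(place, label): n}``.

    Read and inhibitor arcs never alter markings.  Raises if called on a
    disabled transition.
    """
    if not enabled(transition, net):
        raise RuntimeError(f"transition {transition.name!r} fired while disabled")
    delta: dict[tuple[str, str], int] = {}
    for arc in transition.arcs:
        place = net.places[arc.place]
        if arc.kind == ARC_INPUT:
            for label, n in _consume(place, arc.label, arc.weight, rng):
                delta[(arc.place, label)] = delta.get((arc.place, label), 0) - n
        elif arc.kind == ARC_OUTPUT:
            label = arc.label if arc.label is not None else BLACK
            place.add(label, arc.weight)
            delta[(arc.place, label)] = delta.get((arc.place, label), 0) + arc.weight
    return delta


def effective_p(transition: Transition, default_p: float) -> float:
    return transition.p if transition.p is not None else default_p


def channel_due(model: NwnModel, channel: Channel, tick: int) -> bool:
    return all(
        tick % model.net(net_name).transitions[trans_name].timescale == 0
        for net_name, trans_name in channel.endpoints
    )


def channel_enabled(model: NwnModel, channel: Channel) -> bool:
    """A channel is enabled only when every endpoint is locally enabled."""
    return all(
        enabled(model.net(net_name).transitions[trans_name], model.net(net_name))
        for net_name, trans_name in channel.endpoints
    )


def fire_channel(
    model: NwnModel, channel: Channel, rng: Optional[np.random.Generator] = None
) -> dict[tuple[str, str, str], int]:
    """Atomically fire all channel endpoints; delta keyed by (net, place, label)."""
    if not channel_enabled(model, channel):
        raise RuntimeError(f"channel {channel.id!r} fired while not enabled")
    delta: dict[tuple[str, str, str], int] = {}
    for net_name, trans_name in channel.endpoints:
        net = model.net(net_name)
        local = fire(net.transitions[trans_name], net, rng)
        for (place, label), n in local.items():
            key = (net_name, place, label)
            delta[key] = delta.get(key, 0) + n
    return delta


# --- cross-level marking mirroring -----------------------------------------

def snapshot_bindings(model: NwnModel) -> dict[MirrorBinding, dict[str, int]]:
    """Record the current filtered counts of every binding's upper place."""
    return {
        b: {label: model.place(b.upper).count(label) for label in b.labels}
        for b in model.bindings
    }


def mirror(
    model: NwnModel,
    binding: MirrorBinding,
    baseline: dict[str, int],
) -> dict[str, int]:
    """Re-satisfy one binding given its last agreed counts; returns new baseline.

    Whichever side changed since ``baseline`` is the source of truth; on a
    conflicting simultaneous change the upper level wins (with a warning).
    """
    upper = model.place(binding.upper)
    lower = model.place(binding.lower)
    agreed: dict[str, int] = {}
    for label in sorted(binding.labels):
        base = baseline.get(label, 0)
        d_up = upper.count(label) - base
        d_low = lower.count(label) - base
        if d_up and d_low and d_up != d_low:
            logger.warning(
                "mirror conflict on %s/%s label %r (upper %+d, lower %+d): upper wins",
                binding.upper, binding.lower, label, d_up, d_low,
            )
            value = upper.count(label)
        elif d_up and d_low:
            value = base + d_up  # both applied the same change
        else:
            value = max(0, base + d_up + d_low)
        for place in (upper, lower):
            have = place.count(label)
            if have < value:
                place.add(label, value - have)
            elif have > value:
                place.remove(label, have - value)
        agreed[label] = value
    return agreed


def _sync_all(model: NwnModel, baselines: dict) -> None:
    for binding in model.bindings:
        baselines[binding] = mirror(model, binding, baselines[binding])


# --- tick step --------------------------------------------------------------

def step(
    model: NwnModel,
    tick: int,
    streams: SeededStreams,
    default_p: float = DEFAULT_FIRING_PROBABILITY,
) -> list[FireEvent]:
    """Advance the whole two-level model by one simulator tick.

    Returns the list of firing events ``(net name, transition/channel id,
    tick)`` in the order they occurred.
    """
    if tick < 1:
        raise ValueError("tick must be >= 1")
    events: list[FireEvent] = []
    fired_channels: set[str] = set()
    baselines = snapshot_bindings(model)

    for net in model.nets():
        due = [
            t for t in net.transitions.values() if tick % t.timescale == 0
        ]
        if due:
            rng = streams.stream("net", net.name)
            ranked = sorted(due, key=lambda t: t.name)
            order = [ranked[i] for i in rng.permutation(len(ranked))]
            for transition in order:
                if transition.channel is not None:
                    channel = model.channels[transition.channel]
                    if channel.id in fired_channels:
                        continue
                    if not channel_due(model, channel, tick):
                        continue
                    if channel_enabled(model, channel):
                        if rng.random() < effective_p(transition, default_p):
                            fire_channel(model, channel, rng)
                            fired_channels.add(channel.id)
                            events.append((net.name, channel.id, tick))
                else:
                    if enabled(transition, net):
                        if rng.random() < effective_p(transition, default_p):
                            fire(transition, net, rng)
                            events.append((net.name, transition.name, tick))
        _sync_all(model, baselines)

    _sync_all(model, baselines)
    return events
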