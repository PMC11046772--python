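"""Brute-force reachability enumeration for small nets (test oracle).

Independent of the stochastic engine: successors are computed directly
from the arc definitions by exhaustive enumeration of consumption choices.
"""
from __future__ import annotations

import itertools
from collections import Counter, deque
from dataclasses import dataclass

from .net import ARC_INHIBITOR, ARC_INPUT, ARC_OUTPUT, ARC_READ, BLACK, Net

Marking = tuple[tuple[str, str, int], ...]  # sorted (place, label, count), count > 0


def freeze_marking(net: Net) -> Marking:
    return tuple(
        sorted(
            (place.name, label, count)
            for place in net.places.values()
            for label, count in place.marking.items()
            if count > 0
        )
    )


def _as_counters(marking: Marking) -> dict[str, Counter]:
    by_place: dict[str, Counter] = {}
    for place, label, count in marking:
        by_place.setdefault(place, Counter())[label] = count
    return by_place


def _freeze(by_place: dict[str, Counter]) -> Marking:
    return tuple(
        sorted(
            (place, label, count)
            for place, counts in by_place.items()
            for label, count in counts.items()
            if count > 0
        )
    )


def _consumption_options(counts: Counter, label, weight: int):
    """All distinct multisets of ``weight`` tokens matching ``label``."""
    if label is not None:
        if counts[label] >= weight:
            yield Counter({label: weight})
        return
    labels = sorted(l for l, n in counts.items() if n > 0)
    for combo in itertools.combinations_with_replacement(labels, weight):
        pick = Counter(combo)
        if all(counts[l] >= n for l, n in pick.items()):
            yield pick


def _successors(net: Net, marking: Marking):
    by_place = _as_counters(marking)

    def count(place: str, label) -> int:
        counts = by_place.get(place, Counter())
        return sum(counts.values()) if label is None else counts[label]

    for transition in sorted(net.transitions.values(), key=lambda t: t.name):
        ok = True
        for arc in transition.arcs:
            c = count(arc.place, arc.label)
            if arc.kind in (ARC_INPUT, ARC_READ) and c < arc.weight:
                ok = False
            elif arc.kind == ARC_INHIBITOR and c >= arc.weight:
                ok = False
        if not ok:
            continue
        input_arcs = [a for a in transition.arcs if a.kind == ARC_INPUT]
        option_sets = [
            list(_consumption_options(by_place.get(a.place, Counter()), a.label, a.weight))
            for a in input_arcs
        ]
        for choice in itertools.product(*option_sets):
            succ = {p: Counter(c) for p, c in by_place.items()}
            feasible = True
            for arc, pick in zip(input_arcs, choice):
                counts = succ.setdefault(arc.place, Counter())
                for label, n in pick.items():
                    if counts[label] < n:
                        feasible = False
                        break
                    counts[label] -= n
                if not feasible:
                    break
            if not feasible:
                continue
            for arc in transition.arcs:
                if arc.kind == ARC_OUTPUT:
                    label = arc.label if arc.label is not None else BLACK
                    succ.setdefault(arc.place, Counter())[label] += arc.weight
            yield _freeze(succ)


@dataclass(frozen=True)
class ReachabilityResult:
    markings: frozenset[Marking]
    complete: bool  # False when the depth bound truncated the search


def reachable_markings(
    net: Net,
    depth_bound: int = 50,
    max_markings: int = 100_000,
) -> ReachabilityResult:
    """Breadth-first enumeration of all markings reachable within ``depth_bound``."""
    start = freeze_marking(net)
    seen: set[Marking] = {start}
    frontier = deque([(start, 0)])
    truncated = False
    while frontier:
        marking, depth = frontier.popleft()
        if depth >= depth_bound:
            if any(s not in seen for s in _successors(net, marking)):
                truncated = True
            continue
        for succ in _successors(net, marking):
            if succ not in seen:
                if len(seen) >= max_markings:
                    truncated = True
                    continue
                seen.add(succ)
                frontier.append((succ, depth + 1))
    return ReachabilityResult(markings=frozenset(seen), complete=not truncated)
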