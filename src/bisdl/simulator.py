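"""Discrete-time stochastic execution with stimulus schedules and trace recording.

A run executes ``nstep`` ticks.  At each tick every due stimulus schedule
adds a uniform random number of tokens (0..r) to its target place, then the
whole two-level model advances one engine step, then the marking of every
observed place is recorded.  Runs are fully determined by the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .nwn_core import DEFAULT_FIRING_PROBABILITY, NwnModel, SeededStreams, step
from .nwn_core.engine import FireEvent

__all__ = ["SimConfig", "StimulusSchedule", "Trace", "run", "apply_stimulus", "summarize"]


@dataclass(frozen=True)
class SimConfig:
    nstep: int
    seed: int = 0
    default_p: float = DEFAULT_FIRING_PROBABILITY
    mode: str = "exploration"  # or "fixed-axes"; affects plotting only
    draw_nets: bool = False

    def __post_init__(self):
        if self.nstep < 1:
            raise ValueError("nstep must be >= 1")
        if not (0.0 <= self.default_p <= 1.0):
            raise ValueError("default_p must lie in [0, 1]")
        if self.mode not in ("exploration", "fixed-axes"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class StimulusSchedule:
    """Every ``n`` ticks, add u ~ U{0..r} tokens to the target place."""

    scope: str
    place: str
    n: int
    r: int
    label: Optional[str] = None  # token colour; defaults to the place name

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("stimulus period n must be >= 1")
        if self.r < 0:
            raise ValueError("stimulus amplitude r must be >= 0")


@dataclass
class Trace:
    """Per-tick token counts plus the ordered firing-event log."""

    records: list[tuple[int, str, str, int]] = field(default_factory=list)
    events: list[FireEvent] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["tick", "scope", "place", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def series(self, scope: str, place: str) -> pd.Series:
        df = self.to_frame()
        sel = df[(df["scope"] == scope) & (df["place"] == place)]
        return sel.set_index("tick")["count"]

    def channel_firings(self, channel_id: str) -> list[int]:
        """Ticks at which the given channel (or transition) fired."""
        return [tick for _, name, tick in self.events if name == channel_id]


def apply_stimulus(
    model: NwnModel, schedule: StimulusSchedule, tick: int, rng: np.random.Generator
) -> int:
    """Apply one schedule at one tick; returns the number of tokens added."""
    if tick % schedule.n != 0:
        return 0
    place = model.scope_nets[schedule.scope].places[schedule.place]
    added = int(rng.integers(0, schedule.r + 1))
    if added:
        place.add(schedule.label or schedule.place, added)
    return added


def _observed_places(model: NwnModel) -> list[tuple[str, str]]:
    pairs = [
        (net_name, place_name)
        for net_name in sorted(model.scope_nets)
        for place_name in sorted(model.scope_nets[net_name].places)
    ]
    pairs.extend((model.top_net.name, p) for p in sorted(model.top_net.places))
    return pairs


def run(
    model: NwnModel,
    config: SimConfig,
    stimuli: Iterable[StimulusSchedule] = (),
) -> Trace:
    """Execute the model for ``config.nstep`` ticks; the model is mutated in place."""
    stimuli = list(stimuli)
    for schedule in stimuli:
        if schedule.scope not in model.scope_nets:
            raise KeyError(f"stimulus target scope {schedule.scope!r} not in model")
        if schedule.place not in model.scope_nets[schedule.scope].places:
            raise KeyError(
                f"stimulus target place {schedule.place!r} not in scope {schedule.scope!r}"
            )
    streams = SeededStreams(config.seed)
    observed = _observed_places(model)
    trace = Trace()
    for tick in range(1, config.nstep + 1):
        for schedule in stimuli:
            rng = streams.stream("stimulus", schedule.scope, schedule.place)
            apply_stimulus(model, schedule, tick, rng)
        trace.events.extend(step(model, tick, streams, default_p=config.default_p))
        for net_name, place_name in observed:
            count = model.net(net_name).places[place_name].count()
            trace.records.append((tick, net_name, place_name, count))
    return trace


def summarize(trace: Trace, terminal_frac: float = 0.2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy long table plus terminal-window (last ``terminal_frac``) means."""
    df = trace.to_frame()
    if df.empty:
        raise ValueError("empty trace")
    last_tick = df["tick"].max()
    window_start = int(np.floor(last_tick * (1.0 - terminal_frac))) + 1
    terminal = (
        df[df["tick"] >= window_start]
        .groupby(["scope", "place"], as_index=False)["count"]
        .mean()
        .rename(columns={"count": "terminal_mean"})
    )
    return df, terminal


def terminal_mean(trace: Trace, scope: str, place: str, terminal_frac: float = 0.2) -> float:
    _, terminal = summarize(trace, terminal_frac)
    sel = terminal[(terminal["scope"] == scope) & (terminal["place"] == place)]
    if sel.empty:
        raise KeyError(f"no observations for {scope}/{place}")
    return float(sel["terminal_mean"].iloc[0])
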