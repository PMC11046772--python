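"""YAML run configuration mirroring SimConfig / StimulusSchedule field names."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from ..simulator import SimConfig, StimulusSchedule


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> tuple[SimConfig, list[StimulusSchedule], dict]:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {"nstep", "seed", "default_p", "mode", "draw_nets", "stimuli"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        config = SimConfig(
            nstep=int(raw.get("nstep", 100)),
            seed=int(raw.get("seed", 0)),
            default_p=float(raw.get("default_p", 0.6)),
            mode=raw.get("mode", "exploration"),
            draw_nets=bool(raw.get("draw_nets", False)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    stimuli = []
    for i, entry in enumerate(raw.get("stimuli") or []):
        if not isinstance(entry, dict) or not {"scope", "place", "n", "r"} <= set(entry):
            raise ConfigError(f"stimulus #{i} must define scope, place, n, r")
        stimuli.append(
            StimulusSchedule(
                scope=str(entry["scope"]),
                place=str(entry["place"]),
                n=int(entry["n"]),
                r=int(entry["r"]),
                label=entry.get("label"),
            )
        )
    return config, stimuli, raw


def dump_config(config: SimConfig, stimuli: list[StimulusSchedule]) -> str:
    doc = {
        "nstep": config.nstep,
        "seed": config.seed,
        "default_p": config.default_p,
        "mode": config.mode,
        "draw_nets": config.draw_nets,
        "stimuli": [
            {"scope": s.scope, "place": s.place, "n": s.n, "r": s.r}
            for s in stimuli
        ],
    }
    return yaml.safe_dump(doc, sort_keys=True)


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_manifest(
    version: str, inputs: dict[str, str], seed: int, config_echo: dict, outputs: list[str]
) -> str:
    return json.dumps(
        {
            "tool_version": version,
            "input_digests": inputs,
            "seed": seed,
            "config": config_echo,
            "outputs": sorted(outputs),
        },
        indent=2,
        sort_keys=True,
    ) + "\n"
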