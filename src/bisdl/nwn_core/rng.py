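"""Seed handling: one root seed, per-stream generators keyed by stable names.

Substreams are derived from CRC32 hashes of their key strings so that the
random state consumed by one net never depends on dict iteration order or
on which other nets exist.
"""
from __future__ import annotations

import zlib

import numpy as np


def _key_hash(*parts: str) -> int:
    return zlib.crc32("/".join(parts).encode("utf-8"))


class SeededStreams:
    """Lazily created, persistent per-key :class:`numpy.random.Generator` streams."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._streams: dict[tuple[str, ...], np.random.Generator] = {}

    def stream(self, *parts: str) -> np.random.Generator:
        key = tuple(parts)
        if key not in self._streams:
            self._streams[key] = np.random.default_rng(
                np.random.SeedSequence(entropy=self.seed, spawn_key=(_key_hash(*parts),))
            )
        return self._streams[key]
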