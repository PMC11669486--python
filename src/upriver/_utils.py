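"""Shared helpers: seeded substreams and config hashing."""

from __future__ import annotations

import hashlib
import json
import zlib

import numpy as np

__all__ = ["substream", "config_hash"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a named, reproducible random substream derived from a base seed.

    Each (seed, label) pair yields an independent generator, so pipeline
    stages can draw randomness without interfering with each other.
    """
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:12]
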