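"""Seed-substream derivation: one top-level seed, named per-stage streams."""

from __future__ import annotations

import hashlib

import numpy as np


def substream_seed(seed: int, name: str) -> int:
    """Derive a stable 63-bit seed for stage ``name`` from the master seed."""
    digest = hashlib.sha256(f"{name}:{seed}".encode()).digest()
    return int.from_bytes(digest[:8], "big") >> 1


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator whose state depends only on (seed, name)."""
    return np.random.default_rng(substream_seed(seed, name))
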