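"""Seed-substream management.

A single user-facing seed is expanded into named, independent substreams so
that every stochastic stage (null permutations, weight init, dropout,
negative sampling, splits) is reproducible in isolation: re-running one stage
never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent generator for (seed, name)."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def substream_seed(seed: int, name: str) -> int:
    """Scalar seed (< 2**31) for libraries that take an integer state."""
    return int((int(seed) * 1000003 + zlib.crc32(name.encode())) % (2**31))
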