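"""Deterministic seed derivation.

Every stochastic component derives its RNG from a single master seed plus a
string tag, so stages (and individual CV folds) can be re-run in isolation
with identical results.  Tags are hashed with CRC-32, which is stable across
platforms and Python versions (unlike ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["subseed", "rng_for"]

_MOD = 2**31 - 1


def subseed(master: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from ``master`` and a sequence of tags."""
    h = int(master) % _MOD
    for tag in tags:
        h = (h * 1_000_003 + zlib.crc32(str(tag).encode("utf-8"))) % _MOD
    return h


def rng_for(master: int, *tags: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded from :func:`subseed`."""
    return np.random.default_rng(subseed(master, *tags))
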