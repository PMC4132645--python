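"""Deterministic per-stage random streams.

Every stochastic operation takes an integer seed and derives an isolated
``numpy`` Generator from it, optionally namespaced by stage tokens, so that
pipelines are bit-reproducible and no global RNG state is ever touched.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "derive_seed"]


def derive_seed(seed: int, *tokens) -> int:
    """Derive a child seed (< 2**31) from a base seed and stage tokens."""
    h = zlib.crc32(repr(tuple(tokens)).encode())
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def spawn_rng(seed: int, *tokens) -> np.random.Generator:
    """A Generator seeded by ``seed`` namespaced with ``tokens``."""
    if tokens:
        seed = derive_seed(seed, *tokens)
    return np.random.default_rng(int(seed) & 0x7FFFFFFF)
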