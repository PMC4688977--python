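"""Seed management.

All randomness in the package flows from one user-facing integer seed.
Independent operations draw from named substreams derived with
``numpy.random.SeedSequence`` so that adding a draw to one stage never
perturbs another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _tag_key(tag: str) -> int:
    # stable across processes and python versions (unlike hash())
    return zlib.crc32(tag.encode("utf-8"))


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Return a Generator for the substream named by ``tags`` under ``seed``."""
    key = tuple(_tag_key(t) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def spawn_seed(seed: int, *tags: str) -> int:
    """Derive a child integer seed (< 2**31) for a named substream."""
    key = tuple(_tag_key(t) for t in tags)
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))
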