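"""Named random-number substreams.

A master integer seed spawns independent, reproducible child generators keyed
by (tag, indices), so e.g. changing the number of permutations never perturbs
the per-fold bootstrap draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _tag_int(tag: str) -> int:
    return zlib.crc32(tag.encode("utf-8"))


def substream(seed: int, tag: str, *indices: int) -> np.random.Generator:
    """Return a Generator for the substream named by ``tag`` and ``indices``."""
    key = [int(seed) & 0x7FFFFFFF, _tag_int(tag)] + [int(i) for i in indices]
    return np.random.default_rng(np.random.SeedSequence(key))


def child_seed(seed: int, tag: str, *indices: int) -> int:
    """Derive a plain integer seed (< 2**31) for the named substream."""
    key = [int(seed) & 0x7FFFFFFF, _tag_int(tag)] + [int(i) for i in indices]
    return int(np.random.SeedSequence(key).generate_state(1)[0] & 0x7FFFFFFF)
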