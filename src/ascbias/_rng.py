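"""Deterministic random-stream derivation.

All randomness in the package flows from one root seed. Each stochastic stage
derives its own generator from the root seed plus a stage tag, so stages are
individually reproducible and mutually independent.
"""

from __future__ import annotations

import zlib

import numpy as np


def _tag_to_int(tag) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf8"))


def substream(seed: int, *tags) -> np.random.Generator:
    """Generator for stage ``tags`` derived from the root ``seed``."""
    entropy = [int(seed) & 0xFFFFFFFF] + [_tag_to_int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derived_seed(seed: int, tag) -> int:
    """A plain integer seed (< 2^31) derived from the root seed and a tag."""
    return (int(seed) + _tag_to_int(tag)) % (2**31)
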