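"""Counter-based seed splitting.

Every stochastic stage derives its generator from one integer seed plus a
string tag, so independent stages never share streams and adding a stage
never perturbs existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, tag: str) -> int:
    """Derive a stable 31-bit child seed from (seed, tag)."""
    h = zlib.crc32(f"{seed}:{tag}".encode())
    return int(h & 0x7FFFFFFF)


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """Independent Generator for a named stage of a seeded computation."""
    return np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode()))))
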