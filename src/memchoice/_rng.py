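"""Seed plumbing: one root seed, named substreams per stage.

Every stochastic stage draws from ``substream(root_seed, name)`` so any
stage can be regenerated in isolation without consuming another stage's
stream. The name hash is CRC32-based and therefore stable across
processes and Python versions (unlike ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(root_seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named substream."""
    if root_seed < 0:
        raise ValueError("root_seed must be non-negative")
    return (int(root_seed) ^ zlib.crc32(name.encode("utf-8"))) % (2**31)


def substream(root_seed: int, name: str) -> np.random.Generator:
    """A Generator seeded from (root_seed, name), independent per name."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(root_seed), spawn_key=(zlib.crc32(name.encode("utf-8")),))
    )
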