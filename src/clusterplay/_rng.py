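"""Deterministic random-stream management.

Every source of randomness in the package flows from a single master seed.
Named substreams are derived with :class:`numpy.random.SeedSequence` spawn
keys built from stable CRC32 hashes of string tags, so each module
(cluster assignment, connectivity, per-environment weights, per-session
simulation noise, shuffles) is independently reproducible: regenerating one
stream never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "kernel_seed"]


def _tag_key(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def substream(seed: int, *tags: object) -> np.random.Generator:
    """Return a reproducible generator for the stream named by ``tags``.

    Parameters
    ----------
    seed
        Master seed of the experiment or network.
    *tags
        Stream name components (strings or small ints), e.g.
        ``("connectivity",)`` or ``("session", "sleep", 0)``.
    """
    key = tuple(_tag_key(t) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def kernel_seed(rng: np.random.Generator) -> int:
    """Draw a nonzero 64-bit state for the simulator's inline generator."""
    s = 0
    while s == 0:
        s = int(rng.integers(1, 2**63, dtype=np.int64))
    return s
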