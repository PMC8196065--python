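"""Deterministic random-stream derivation.

Every stochastic component of the package draws from a substream derived
from a single user-supplied integer seed plus a tuple of labels (strings or
integers).  Labels are hashed with CRC32 so the mapping is stable across
sessions and platforms; identical (seed, labels) always yield an identical
`numpy.random.Generator`.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    Parameters
    ----------
    seed:
        The run-level seed.
    *keys:
        Arbitrary labels (e.g. ``("noise", frame_index)``) distinguishing
        independent substreams of the same run.
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
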