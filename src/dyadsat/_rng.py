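"""Named, reproducible random substreams.

Every source of randomness in the package derives from a single integer
seed through :func:`substream`, so two runs with the same configuration are
bit-identical and independent stages never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys``.

    Parameters
    ----------
    seed
        Master seed (any non-negative integer below 2**31).
    *keys
        Hashable labels (strings, ints) identifying the stream, e.g.
        ``substream(seed, "null", 17)``.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        entropy.append(zlib.crc32(repr(key).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))
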