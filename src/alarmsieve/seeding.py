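"""Named substreams derived from a single global seed.

Every source of randomness in the package (simulator, weight init, fold
splitting, baseline resampling, dropout) draws from its own named stream so
that toggling one component never shifts another component's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_seed"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def stream_seed(seed: int, *keys: object) -> np.random.SeedSequence:
    """Build a :class:`~numpy.random.SeedSequence` for a named substream."""
    return np.random.SeedSequence([int(seed)] + [_key_to_int(k) for k in keys])


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a generator seeded by ``seed`` and a tuple of stream names.

    Same ``(seed, keys)`` always yields an identical stream; different key
    tuples yield statistically independent streams.
    """
    return np.random.default_rng(stream_seed(seed, *keys))
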