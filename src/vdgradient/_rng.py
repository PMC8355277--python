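"""Deterministic named random substreams.

Every stochastic stage draws from its own substream of one master seed, so
trial generation, weight draws, spike draws and decoder resampling are
seed-isolated: changing the number of draws in one stage never perturbs
another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _tag_to_int(tag: object) -> int:
    return zlib.crc32(str(tag).encode("utf-8"))


def substream(master_seed: int, *tags: object) -> np.random.Generator:
    """Return a Generator keyed by ``(master_seed, *tags)``.

    Tags may be strings or integers; the same tag tuple always yields an
    identical stream, and distinct tag tuples yield independent streams.
    """
    entropy = [int(master_seed) & 0xFFFFFFFF] + [_tag_to_int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))
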