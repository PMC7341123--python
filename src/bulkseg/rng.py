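"""Named random substreams.

Every stochastic stage (meiosis, phenotype draw, bulk sampling, read
sampling, null-band simulation) pulls its generator from a named substream
of one master seed, so a stage can be reproduced in isolation and adding a
stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from `seed`.

    The stream key is a CRC32 of the stage name, so the mapping is stable
    across sessions and platforms.
    """
    entropy = (int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))
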