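"""Seeded random substreams.

All stochastic code in the package draws from a generator obtained through
:func:`substream`, so each named consumer gets an independent stream derived
from one top-level seed.  Adding a new generator therefore never perturbs the
draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator seeded from ``seed`` and the stream label ``name``.

    Deterministic: the same (seed, name) pair always yields the same stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
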