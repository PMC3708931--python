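"""Seed fan-out: one global seed, independent named substreams.

Every stage/platform draws from its own `numpy` Generator keyed by
``(seed, label, ...)`` so adding one consumer never perturbs another.
Labels are hashed with CRC32, which is stable across processes and
Python versions (unlike the builtin ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels`` under ``seed``."""
    entropy = [int(seed) & 0xFFFFFFFF]
    entropy.extend(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))
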