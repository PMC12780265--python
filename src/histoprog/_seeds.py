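"""Deterministic seed derivation for the multi-stage pipeline.

All randomness in a run flows from one integer seed.  Each stage draws its
own child seed from ``child_seed(seed, *path)``, where ``path`` is a tuple of
stage labels (strings or small integers).  The rule is: hash each label with
CRC-32 and feed ``(seed, h1, h2, ...)`` as the entropy of a
``numpy.random.SeedSequence``; the first generated state word, folded into
``[0, 2**31)``, is the child seed.  Distinct paths therefore yield
independent, reproducible streams.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, *path: str | int) -> int:
    """Derive a child seed for stage ``path`` from a master ``seed``."""
    entropy = [int(seed) & 0xFFFFFFFF]
    for part in path:
        if isinstance(part, (int, np.integer)):
            entropy.append(int(part) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(part).encode("utf-8")))
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def child_rng(seed: int, *path: str | int) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded for stage ``path``."""
    return np.random.default_rng(child_seed(seed, *path))
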