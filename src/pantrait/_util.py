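"""Small shared helpers: seeding, logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("pantrait")


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-stage seed from a global seed and a stage name.

    Uses CRC32 so the derivation is independent of Python's hash
    randomization and of the order in which stages run.  Result < 2**31.
    """
    return (zlib.crc32(f"{int(seed)}:{name}".encode()) ^ int(seed)) & 0x7FFFFFFF


def rng_for(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, name))
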