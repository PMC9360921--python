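"""Deterministic seed derivation.

Every stochastic stage takes an explicit integer seed.  Stage seeds are
derived from a master seed with a counter scheme so that a run manifest
(master seed + stage name + counter) reproduces every draw bit-for-bit.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed", "rng_from"]

import numpy as np


def derive_seed(master_seed: int, stage: str, counter: int = 0) -> int:
    """Derive a sub-seed < 2**31 from a master seed, stage label and counter.

    Uses SHA-256 over the triple so that distinct stages and counters give
    independent, reproducible streams regardless of platform.
    """
    key = f"{int(master_seed)}:{stage}:{int(counter)}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rng_from(seed: int) -> np.random.Generator:
    """A PCG64 generator from an explicit integer seed."""
    return np.random.default_rng(int(seed))
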