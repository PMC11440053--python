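"""Deterministic seed fan-out.

A single user-facing seed is expanded into independent per-stage seeds by
hashing the stage name together with the seed.  Stages therefore draw from
independent streams regardless of the order in which they run.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MAX_SEED = 2**31 - 1


def derive_seed(seed: int, name: str) -> int:
    """Derive a stable sub-seed (< 2^31) for a named stage."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % _MAX_SEED


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for a named stage, independent of other stages."""
    return np.random.default_rng(derive_seed(seed, name))
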