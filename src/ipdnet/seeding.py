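"""Deterministic seed derivation.

A single experiment seed fans out to per-purpose child seeds (stimulus
sampling, weight initialisation, training-time stimulus draws, evaluation
draws, ...) by stable hashing of ``(seed, stage name)``.  Adding a new stage
never perturbs the streams of existing ones, and every stage can be
reproduced in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(seed: int, stage: str) -> int:
    """Derive a stable 31-bit child seed for ``stage`` from a root ``seed``."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """A PCG64 generator seeded for one named stage of an experiment."""
    return np.random.default_rng(child_seed(seed, stage))
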