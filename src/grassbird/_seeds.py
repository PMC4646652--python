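"""Hierarchical seed derivation.

All randomness in a run flows from one user-supplied base seed.  Component
seeds are derived by hashing (base, part, part, ...) tuples through
``numpy.random.SeedSequence``, so every (cell, replicate, landscape slot)
gets an independent, reproducible stream and adding replicates never
perturbs earlier ones.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed", "spawn_seeds"]


def derive_seed(*parts: int) -> int:
    """A deterministic 32-bit seed derived from a tuple of integer parts."""
    entropy = [int(p) & 0xFFFFFFFF for p in parts]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


def spawn_seeds(base: int, n: int) -> list[int]:
    """``n`` independent child seeds of ``base``."""
    return [derive_seed(base, i) for i in range(n)]
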