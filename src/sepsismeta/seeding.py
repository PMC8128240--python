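"""Seed derivation: every stochastic component draws its seed from a single
run seed through ``numpy.random.SeedSequence`` with a documented key tuple,
so runs are exactly reproducible and sub-streams are independent.

Keys are small non-negative integers (e.g. iteration index, method index);
the derived seed is reduced below 2**31 for consumers that require a plain
integer seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(root: int, *keys: int) -> int:
    """Deterministic child seed for the given key path under ``root``."""
    ss = np.random.SeedSequence(entropy=(int(root), *map(int, keys)))
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(root: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(root), *map(int, keys)))
    )
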