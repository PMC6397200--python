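"""Seed handling: every stochastic function accepts an int seed, a
``numpy.random.SeedSequence`` or an already-built ``Generator``; cohort-level
functions spawn one independent child stream per unit so whole cohorts are
reproducible from a single seed."""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def as_rng(seed) -> np.random.Generator:
    """Return a ``Generator`` for *seed* (int, SeedSequence or Generator)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """Spawn *n* independent child seed sequences from *seed*."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        # Derive a child sequence from the generator's bit stream.
        ss = np.random.SeedSequence(int(seed.integers(0, 2**31 - 1)))
    else:
        ss = np.random.SeedSequence(seed)
    return ss.spawn(n)
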