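"""Seed handling shared across the package.

One master seed; independent per-worm / per-replicate streams are derived
with ``numpy.random.SeedSequence.spawn`` so ensembles are reproducible and
safe to parallelise.
"""

from __future__ import annotations

import numpy as np


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from an int seed, SeedSequence, or Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from a master seed."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
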