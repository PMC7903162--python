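"""Deterministic seed management.

One master seed per run; every stage (packing, directions, node cloud,
growth order, per-fibre randomness, dynamic insertion) draws from its own
child of the master ``SeedSequence`` so stages are independently
reproducible and insensitive to each other's consumption.
"""

from __future__ import annotations

import numpy as np

# fixed stage labels -> spawn key offsets
STAGES = (
    "packing",
    "directions",
    "nodes",
    "growth_order",
    "growth",
    "dynamic",
    "optimise",
)


def stage_rngs(master_seed: int) -> dict[str, np.random.Generator]:
    """Return one independent Generator per pipeline stage."""
    ss = np.random.SeedSequence(int(master_seed))
    children = ss.spawn(len(STAGES))
    return {name: np.random.default_rng(c) for name, c in zip(STAGES, children)}


def rng_from(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
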