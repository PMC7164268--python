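"""Deterministic seeding helpers.

A single master seed spawns an independent child stream per replicate index
via ``SeedSequence(master, spawn_key=(index,))``, so replicate *r* is
reproducible regardless of how many replicates are requested in total.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

RngLike = Union[int, np.random.Generator, None]


def as_generator(seed: RngLike) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_rng(master_seed: Optional[int], index: int) -> np.random.Generator:
    """Independent, reproducible stream for replicate ``index``."""
    if master_seed is None:
        return np.random.default_rng()
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return np.random.default_rng(ss)
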