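"""SERES random walks over the sites of a fixed multiple sequence alignment.

The walk lives on the column indices ``0..k-1`` of an alignment.  A start
site and a travel direction are drawn uniformly at random; the walk then
repeatedly *emits* the current site, reverses direction — with certainty
when the next step in the travel direction would leave the alignment, and
otherwise with reversal probability ``gamma`` — and moves one site.  It
stops once ``target_length`` sites (by default exactly ``k``, the input
alignment length) have been emitted.

The two deterministic ``gamma = 0`` walks started at the alignment ends are
exactly the Heads-or-Tails (HoT) pair: the left-to-right walk reproduces
the input and the right-to-left walk its column reversal.  Every emitted
trace preserves neighbors: consecutive sampled sites are adjacent columns
of the input, which is the property that lets resampling respect
intra-sequence dependence (unlike the i.i.d. column bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._rng import RngLike, as_generator
from .io import MultipleAlignment

Direction = Union[str, int]


def _as_step(direction: Direction) -> int:
    """Normalize 'L'/'R'/±1 into a step of -1 or +1."""
    if direction in (1, +1, "R", "r", "right"):
        return 1
    if direction in (-1, "L", "l", "left"):
        return -1
    raise ValueError(f"invalid direction {direction!r}")


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of an aligned-site walk.

    gamma:
        Reversal probability in [0, 1].  0.5 makes each step's direction an
        independent uniform coin flip; 0 gives deterministic sweeps (the
        HoT special cases).
    seed:
        Seed or Generator for the walk's randomness.
    target_length:
        Number of sites to emit; ``None`` means the alignment length k.
    """

    gamma: float = 0.5
    seed: RngLike = None
    target_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.target_length is not None and self.target_length < 1:
            raise ValueError("target_length must be >= 1")


@dataclass(frozen=True)
class ResamplingTrace:
    """Ordered 0-based site indices emitted by one walk."""

    indices: tuple[int, ...]
    k: int

    def __post_init__(self) -> None:
        if any(i < 0 or i >= self.k for i in self.indices):
            raise ValueError("trace index out of range")

    def __len__(self) -> int:
        return len(self.indices)


def sample_aligned_trace(
    k: int,
    cfg: WalkConfig,
    start: Optional[int] = None,
    direction: Optional[Direction] = None,
) -> ResamplingTrace:
    """Run one site walk on an alignment of length ``k``.

    Each step emits the current site, then flips the travel direction (with
    certainty at the boundary the walk is moving toward, else with
    probability ``cfg.gamma``), then moves one site.  ``start`` and
    ``direction`` override the uniform random draws; they are primarily
    useful for reproducing the deterministic HoT sweeps.
    """
    if k < 1:
        raise ValueError(f"alignment length must be >= 1, got {k}")
    rng = as_generator(cfg.seed)
    length = cfg.target_length if cfg.target_length is not None else k
    if start is None:
        start = int(rng.integers(k))
    elif not 0 <= start < k:
        raise ValueError(f"start {start} outside [0, {k})")
    if direction is None:
        step = 1 if rng.random() < 0.5 else -1
    else:
        step = _as_step(direction)

    if k == 1:
        # Degenerate walk: the single site is emitted repeatedly.
        return ResamplingTrace((0,) * length, k=1)

    out = np.empty(length, dtype=np.intp)
    pos = start
    for t in range(length):
        out[t] = pos
        # the boundary reversal is certain and overrides the gamma draw, so
        # the next move always stays inside [0, k)
        if pos == k - 1:
            step = -1
        elif pos == 0:
            step = 1
        elif cfg.gamma > 0.0 and rng.random() < cfg.gamma:
            step = -step
        pos += step
    return ResamplingTrace(tuple(int(i) for i in out), k=k)


def resample_alignment(
    msa: MultipleAlignment,
    cfg: WalkConfig,
    start: Optional[int] = None,
    direction: Optional[Direction] = None,
) -> tuple[MultipleAlignment, ResamplingTrace]:
    """Column-resample an alignment along one site walk.

    Column ``j`` of the replicate equals column ``trace[j]`` of the input;
    by default the replicate has exactly the input's length.
    """
    trace = sample_aligned_trace(msa.k, cfg, start=start, direction=direction)
    return msa.take_columns(trace.indices), trace


def bootstrap_columns(
    msa: MultipleAlignment,
    rng: RngLike = None,
    n_columns: Optional[int] = None,
) -> tuple[MultipleAlignment, tuple[int, ...]]:
    """Standard bootstrap comparator: sample columns i.i.d. with replacement.

    Returns the resampled alignment and the sampled column indices.  This is
    the classical resampling step SERES replaces; it treats sites as
    independent and identically distributed.
    """
    rng = as_generator(rng)
    n_columns = msa.k if n_columns is None else n_columns
    cols = tuple(int(c) for c in rng.integers(msa.k, size=n_columns))
    return msa.take_columns(cols), cols
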