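"""SERES random walks on barrier space for unaligned sequences.

The walk state is a barrier index.  It starts at a barrier chosen uniformly
at random and travels to a neighboring barrier; on each traversal, every
sequence contributes the residues lying between its two cut points — in
natural order when moving right, in reversed order when moving left, which
is the only orientation that preserves residue adjacency across traversal
boundaries.  Arriving at a trivial (start/end) barrier forces a reversal;
elsewhere the direction reverses with probability ``gamma``.  The walk
stops at the first barrier arrival at which the longest resampled sequence
has reached ``length_factor`` times the longest input sequence length, and
always performs at least one traversal.

Because all sequences share the same traversal schedule (the walk is one
global process over synchronized barriers), the resampled sequences stay
mutually alignable, and residue-level provenance lets replicate homologies
be mapped back onto the original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._rng import RngLike, as_generator
from .aligned_walk import Direction, _as_step
from .anchors import BarrierSet
from .io import Sequence


@dataclass(frozen=True)
class UnalignedWalkConfig:
    """Parameters of a barrier-space walk.

    gamma:
        Reversal probability at non-trivial barriers, in [0, 1].
    length_factor:
        Termination threshold: the longest resampled sequence must reach
        ``length_factor`` x the longest input length (> 0; 1.0 mirrors the
        aligned walk's exact length conservation).
    seed:
        Seed or Generator for the walk's randomness.
    """

    gamma: float = 0.5
    length_factor: float = 1.0
    seed: RngLike = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not self.length_factor > 0:
            raise ValueError("length_factor must be positive")


@dataclass(frozen=True)
class UnalignedReplicate:
    """One resampled replicate of a set of unaligned sequences.

    provenance[s][p] is the index, in original sequence *s*, of the residue
    at position *p* of resampled sequence *s*; within a single barrier
    traversal consecutive provenance indices differ by exactly 1.
    segment_trace records the ordered (barrier_from, barrier_to) traversals.
    """

    sequences: list[Sequence]
    provenance: list[list[int]]
    segment_trace: list[tuple[int, int]]


def sample_unaligned_replicate(
    seqs: list[Sequence],
    barriers: BarrierSet,
    cfg: UnalignedWalkConfig,
    start_barrier: Optional[int] = None,
    direction: Optional[Direction] = None,
) -> UnalignedReplicate:
    """Run one barrier walk and build the resampled replicate.

    ``start_barrier`` and ``direction`` override the uniform random draws
    (a start at a trivial barrier always moves inward).  Termination is
    checked only at barrier arrivals, so whole inter-barrier segments are
    atomic and anchor synchronization is never broken mid-segment.
    """
    if not seqs:
        raise ValueError("no sequences to resample")
    off = barriers.offsets
    m, n = off.shape
    if n != len(seqs):
        raise ValueError("barrier set and sequence list sizes differ")
    lengths = np.array([len(s) for s in seqs], dtype=np.intp)
    if np.any(barriers.sequence_lengths != lengths):
        raise ValueError("final barrier does not match sequence lengths")

    rng = as_generator(cfg.seed)
    if start_barrier is None:
        b = int(rng.integers(m))
    else:
        if not 0 <= start_barrier < m:
            raise ValueError(f"start barrier {start_barrier} outside [0, {m})")
        b = start_barrier
    if b == 0:
        step = 1
    elif b == m - 1:
        step = -1
    elif direction is None:
        step = 1 if rng.random() < 0.5 else -1
    else:
        step = _as_step(direction)

    target = cfg.length_factor * int(lengths.max())
    chars: list[list[str]] = [[] for _ in seqs]
    prov: list[list[int]] = [[] for _ in seqs]
    trace: list[tuple[int, int]] = []
    longest = 0

    while True:
        dest = b + step
        lo_barrier, hi_barrier = (b, dest) if step == 1 else (dest, b)
        for s, seq in enumerate(seqs):
            lo, hi = int(off[lo_barrier, s]), int(off[hi_barrier, s])
            if step == 1:
                rng_idx = range(lo, hi)
            else:
                rng_idx = range(hi - 1, lo - 1, -1)
            for i in rng_idx:
                chars[s].append(seq.residues[i])
                prov[s].append(i)
            longest = max(longest, len(chars[s]))
        trace.append((b, dest))
        b = dest
        if longest >= target:
            # Re-alignment needs every resampled sequence non-empty; keep
            # walking in the rare case a sequence has not been touched yet
            # (skipped when gamma == 1 pins the walk between two barriers).
            if all(chars) or cfg.gamma == 1.0:
                break
        if b == 0 or b == m - 1:
            step = -step
        elif cfg.gamma > 0.0 and rng.random() < cfg.gamma:
            step = -step

    out_seqs = [
        Sequence(seq.id, "".join(c)) for seq, c in zip(seqs, chars)
    ]
    return UnalignedReplicate(out_seqs, prov, trace)


def replicate_provenance_map(rep: UnalignedReplicate) -> list[dict[int, int]]:
    """Per-sequence total map: resampled position -> original residue index."""
    return [
        {p: orig for p, orig in enumerate(entries)}
        for entries in rep.provenance
    ]
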