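"""Anchor estimation on a guide alignment and barrier construction.

Unaligned sequences cannot be resampled column-by-column, so the walk is
synchronized through *anchors*: short, gap-free, high-similarity windows of
a guide alignment.  Similarity is measured by the average normalized
Hamming distance (ANHD) over all sequence pairs, with indels counted as
mismatches.  Each anchor's two column boundaries are converted to one
unaligned cut point per sequence; these synchronized cut points are
*barriers* in the parallel-computing sense, and the unaligned walk moves
from barrier to neighboring barrier.  Two trivial barriers — the start and
the end of the sequences — are always present.

Defaults follow common practice for this procedure: ``floor(k / 20)``
anchors of 5 columns each, separated by at least 25 columns, where *k* is
the guide alignment length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import GAP, MultipleAlignment

DEFAULT_ANCHOR_LENGTH = 5
DEFAULT_MIN_DISTANCE = 25


def default_anchor_count(k: int) -> int:
    """Default number of anchors for a guide alignment of length k."""
    return k // 20


@dataclass(frozen=True)
class Anchor:
    """A gap-free guide-MSA window [start_col, end_col) with its ANHD."""

    start_col: int
    end_col: int
    anhd: float

    def __post_init__(self) -> None:
        if self.end_col <= self.start_col:
            raise ValueError("anchor window must be non-empty")
        if not 0.0 <= self.anhd <= 1.0:
            raise ValueError("anhd must be in [0, 1]")

    @property
    def length(self) -> int:
        return self.end_col - self.start_col


@dataclass(frozen=True)
class BarrierSet:
    """Synchronized per-sequence cut points.

    ``offsets`` has shape (m, n): m barriers by n sequences, each entry a
    0-based offset into that sequence's unaligned residues.  Offsets are
    non-decreasing down each column; the first barrier is all zeros and the
    last equals the sequence lengths (the two trivial barriers).
    """

    offsets: np.ndarray

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=np.intp)
        object.__setattr__(self, "offsets", off)
        if off.ndim != 2 or off.shape[0] < 2:
            raise ValueError("need at least the two trivial barriers")
        if np.any(np.diff(off, axis=0) < 0):
            raise ValueError("barrier offsets must be non-decreasing")
        if np.any(off[0] != 0):
            raise ValueError("first barrier must be all zeros")

    @property
    def m(self) -> int:
        return self.offsets.shape[0]

    @property
    def n_sequences(self) -> int:
        return self.offsets.shape[1]

    @property
    def sequence_lengths(self) -> np.ndarray:
        return self.offsets[-1]


def _window_matrix(msa: MultipleAlignment, start_col: int, length: int) -> np.ndarray:
    rows = [row[start_col : start_col + length] for row in msa.rows]
    return np.array([list(r) for r in rows])


def window_anhd(msa: MultipleAlignment, start_col: int, length: int) -> float:
    """ANHD of the window [start_col, start_col+length) of an alignment.

    Mean, over all C(n, 2) sequence pairs, of the per-pair fraction of
    mismatching columns; any comparison involving a gap (including
    gap-vs-gap) counts as a mismatch.
    """
    if msa.n < 2:
        raise ValueError("ANHD needs at least two sequences")
    if length < 1 or start_col < 0 or start_col + length > msa.k:
        raise ValueError("window outside alignment bounds")
    w = _window_matrix(msa, start_col, length)
    is_gap = w == GAP
    n = msa.n
    total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            mism = (w[a] != w[b]) | is_gap[a] | is_gap[b]
            total += mism.mean()
    return total / (n * (n - 1) / 2)


def _gap_free_starts(msa: MultipleAlignment, length: int) -> np.ndarray:
    """Start columns of fully gap-free windows, via a gap-count prefix sum."""
    mat = np.array([list(row) for row in msa.rows])
    gaps_per_col = (mat == GAP).sum(axis=0)
    if msa.k < length:
        return np.empty(0, dtype=np.intp)
    csum = np.concatenate([[0], np.cumsum(gaps_per_col)])
    window_gaps = csum[length:] - csum[:-length]
    return np.flatnonzero(window_gaps == 0)


def find_anchors(
    guide: MultipleAlignment,
    num_anchors: Optional[int] = None,
    anchor_len: int = DEFAULT_ANCHOR_LENGTH,
    min_dist: int = DEFAULT_MIN_DISTANCE,
) -> list[Anchor]:
    """Greedily select high-similarity anchors on a guide alignment.

    Candidate windows are all fully gap-free windows of ``anchor_len``
    columns.  Candidates are ranked by ascending ANHD (ties broken by
    leftmost start column) and accepted greedily subject to an
    edge-to-edge separation of at least ``min_dist`` columns from every
    previously accepted anchor.  Returns up to ``num_anchors`` anchors
    (default ``floor(k / 20)``), sorted by start column; a warning is
    issued when fewer eligible windows exist than requested.
    """
    if anchor_len < 1:
        raise ValueError("anchor_len must be >= 1")
    if num_anchors is None:
        num_anchors = default_anchor_count(guide.k)
    if num_anchors <= 0:
        return []

    starts = _gap_free_starts(guide, anchor_len)
    ranked = sorted(
        (window_anhd(guide, int(s), anchor_len), int(s)) for s in starts
    )
    chosen: list[Anchor] = []
    for anhd, start in ranked:
        if len(chosen) == num_anchors:
            break
        end = start + anchor_len
        ok = all(
            # edge-to-edge separation between half-open windows
            (start - a.end_col >= min_dist) or (a.start_col - end >= min_dist)
            for a in chosen
        )
        if ok:
            chosen.append(Anchor(start, end, anhd))
    if len(chosen) < num_anchors:
        warnings.warn(
            f"only {len(chosen)} of {num_anchors} requested anchors are "
            "feasible under the gap-free and spacing constraints",
            stacklevel=2,
        )
    return sorted(chosen, key=lambda a: a.start_col)


def anchors_to_barriers(
    guide: MultipleAlignment, anchors: list[Anchor]
) -> BarrierSet:
    """Convert anchor column boundaries into synchronized barriers.

    The barrier at guide column *c* assigns to sequence *s* the count of
    non-gap cells of row *s* in columns [0, c) — i.e. the unaligned offset
    where column *c* cuts that sequence.  Each anchor contributes a barrier
    at its start and end column; the trivial all-zero and all-length
    barriers are prepended/appended, and exact duplicates are dropped.
    """
    for prev, cur in zip(anchors, anchors[1:]):
        if cur.start_col < prev.end_col:
            raise ValueError("anchors overlap or are unsorted")

    mat = np.array([list(row) for row in guide.rows])
    nongap_csum = np.concatenate(
        [np.zeros((guide.n, 1), dtype=np.intp),
         np.cumsum(mat != GAP, axis=1).astype(np.intp)],
        axis=1,
    )  # nongap_csum[s, c] = non-gap cells of row s in columns [0, c)

    cols = [0]
    for a in anchors:
        cols.extend((a.start_col, a.end_col))
    cols.append(guide.k)

    offsets = []
    for c in cols:
        barrier = nongap_csum[:, c]
        if offsets and np.array_equal(offsets[-1], barrier):
            continue
        offsets.append(barrier)
    if len(offsets) == 1:  # all sequences empty cannot happen; all-zero guard
        offsets.append(nongap_csum[:, guide.k])
    return BarrierSet(np.stack(offsets))
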