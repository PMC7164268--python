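"""Residue-pair support estimation from resampled, re-aligned replicates.

Given an input alignment *A* of unaligned sequences *S*, the pipeline
resamples *S* (SERES barrier walks by default, i.i.d. column bootstrap as
the classical comparator), re-aligns every replicate, and scores each
residue-pair homology of *A* by the fraction of replicate alignments that
recover it.  A replicate *supports* a homology ``(s_i, p_i, s_j, p_j)``
when at least one of its alignment columns contains an occurrence of
original residue ``p_i`` of sequence ``s_i`` together with an occurrence of
original residue ``p_j`` of sequence ``s_j`` (resampled sequences can
contain a residue more than once; this binary rule reduces to classical
GUIDANCE-style scoring when each residue is sampled exactly once).

The default denominator counts only replicates in which both residues were
sampled at all, so residues near sequence ends — which the walk visits
slightly less often — are not penalized for never having had a chance;
``denominator_mode="total"`` divides by the full replicate count instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence as TypingSequence

from ._rng import child_rng
from .aligned_walk import bootstrap_columns
from .aligner import AlignerSpec, align_sequences
from .anchors import (
    DEFAULT_ANCHOR_LENGTH,
    DEFAULT_MIN_DISTANCE,
    anchors_to_barriers,
    find_anchors,
)
from .io import GAP, MultipleAlignment, ResiduePair, extract_homologies
from .unaligned_walk import (
    UnalignedWalkConfig,
    sample_unaligned_replicate,
)

#: Default replicate count for support estimation.
DEFAULT_N_REPLICATES = 100


@dataclass
class SupportAnnotation:
    """Support scores on the unit interval for every input-MSA homology."""

    pair_scores: dict[ResiduePair, float]
    n_replicates: int
    denominator_mode: str = "co-sampled"
    n_cosampled: dict[ResiduePair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.denominator_mode not in ("co-sampled", "total"):
            raise ValueError(
                f"unknown denominator mode {self.denominator_mode!r}"
            )
        for pair, s in self.pair_scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} for {pair} outside [0, 1]")

    def mean_support(self, pairs: Optional[Iterable[ResiduePair]] = None) -> float:
        keys = list(self.pair_scores if pairs is None else pairs)
        if not keys:
            raise ValueError("no pairs to average")
        return sum(self.pair_scores[p] for p in keys) / len(keys)


#: One re-aligned replicate: its alignment plus, per row, the ordered list
#: mapping each resampled residue back to its original unaligned index.
ReplicateAlignment = tuple[MultipleAlignment, TypingSequence[TypingSequence[int]]]


def _replicate_pair_sets(
    aln: MultipleAlignment,
    provenance: TypingSequence[TypingSequence[int]],
    wanted: set[ResiduePair],
) -> tuple[set[ResiduePair], list[set[int]]]:
    """Input homologies co-aligned by one replicate, and per-sequence sets of
    sampled original residue indices."""
    sampled = [set(p) for p in provenance]
    supported: set[ResiduePair] = set()
    # residue counters per row walk the replicate alignment left to right
    counters = [0] * aln.n
    for j in range(aln.k):
        cells = []
        for i in range(aln.n):
            ch = aln.rows[i][j]
            if ch != GAP:
                cells.append((aln.ids[i], provenance[i][counters[i]]))
                counters[i] += 1
        for a in range(len(cells)):
            for b in range(a + 1, len(cells)):
                pair = ResiduePair.make(*cells[a], *cells[b])
                if pair in wanted:
                    supported.add(pair)
    return supported, sampled


def pair_support(
    input_msa: MultipleAlignment,
    replicates: TypingSequence[ReplicateAlignment],
    denominator_mode: str = "co-sampled",
) -> SupportAnnotation:
    """Score every homology of the input alignment against replicates.

    ``replicates`` pairs each re-estimated replicate alignment with its
    per-row provenance (resampled position -> original residue index, in
    row-degapped order).  Externally generated replicate alignments (e.g.
    parametrically perturbed ones) can be pooled into the same list, as
    long as their provenance maps are expressed in original coordinates.
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    homologies = extract_homologies(input_msa)
    supported_counts = {p: 0 for p in homologies}
    cosampled_counts = {p: 0 for p in homologies}
    for aln, prov in replicates:
        if set(aln.ids) != set(input_msa.ids):
            raise ValueError("replicate ids do not match the input alignment")
        # reorder provenance to input id order for sampled-set lookups
        row_of = {label: i for i, label in enumerate(aln.ids)}
        supported, sampled_rows = _replicate_pair_sets(aln, prov, homologies)
        sampled = {
            label: sampled_rows[row_of[label]] for label in input_msa.ids
        }
        for pair in homologies:
            co = (
                pair.pos_i in sampled[pair.seq_i]
                and pair.pos_j in sampled[pair.seq_j]
            )
            if co:
                cosampled_counts[pair] += 1
            if pair in supported:
                supported_counts[pair] += 1

    scores: dict[ResiduePair, float] = {}
    for pair in homologies:
        if denominator_mode == "total":
            denom = len(replicates)
        else:
            denom = cosampled_counts[pair]
        scores[pair] = supported_counts[pair] / denom if denom else 0.0
    return SupportAnnotation(
        scores,
        n_replicates=len(replicates),
        denominator_mode=denominator_mode,
        n_cosampled=cosampled_counts,
    )


def seres_replicates(
    input_msa: MultipleAlignment,
    n_replicates: int,
    aligner: AlignerSpec,
    gamma: float = 0.5,
    length_factor: float = 1.0,
    num_anchors: Optional[int] = None,
    anchor_len: int = DEFAULT_ANCHOR_LENGTH,
    min_dist: int = DEFAULT_MIN_DISTANCE,
    guide: Optional[MultipleAlignment] = None,
    seed: Optional[int] = None,
) -> list[ReplicateAlignment]:
    """Generate and re-align ``n_replicates`` SERES barrier-walk replicates.

    The guide alignment for anchor estimation defaults to the input
    alignment itself.
    """
    seqs = input_msa.degap()
    guide = input_msa if guide is None else guide
    anchors = find_anchors(
        guide, num_anchors=num_anchors, anchor_len=anchor_len, min_dist=min_dist
    )
    barriers = anchors_to_barriers(guide, anchors)
    out: list[ReplicateAlignment] = []
    for r in range(n_replicates):
        rng = child_rng(seed, r)
        cfg = UnalignedWalkConfig(
            gamma=gamma, length_factor=length_factor, seed=rng
        )
        rep = sample_unaligned_replicate(seqs, barriers, cfg)
        aln = align_sequences(rep.sequences, aligner)
        out.append((aln, rep.provenance))
    return out


def bootstrap_replicates(
    input_msa: MultipleAlignment,
    n_replicates: int,
    aligner: AlignerSpec,
    seed: Optional[int] = None,
) -> list[ReplicateAlignment]:
    """Classical-bootstrap comparator replicates.

    Columns of the input alignment are sampled i.i.d. with replacement;
    the degapped rows of the column-resampled alignment (whose residues
    carry provenance through the input alignment's cell provenance) are
    then re-aligned exactly like SERES replicates, so the only difference
    between the two pipelines is the resampling scheme.
    """
    prov_in = input_msa.provenance
    out: list[ReplicateAlignment] = []
    for r in range(n_replicates):
        rng = child_rng(seed, r)
        boot, cols = bootstrap_columns(input_msa, rng)
        prov = []
        keep = []
        for i in range(input_msa.n):
            entries = [
                prov_in[i][c] for c in cols if input_msa.rows[i][c] != GAP
            ]
            prov.append(entries)
            keep.append(bool(entries))
        if not all(keep):
            # a row with no sampled residues cannot be re-aligned; redraw
            # deterministically from the same child stream
            while not all(
                any(input_msa.rows[i][c] != GAP for c in cols)
                for i in range(input_msa.n)
            ):
                boot, cols = bootstrap_columns(input_msa, rng)
            prov = [
                [prov_in[i][c] for c in cols if input_msa.rows[i][c] != GAP]
                for i in range(input_msa.n)
            ]
        seqs = boot.degap()
        aln = align_sequences(seqs, aligner)
        out.append((aln, prov))
    return out


def run_support_pipeline(
    input_msa: MultipleAlignment,
    n_replicates: int = DEFAULT_N_REPLICATES,
    method: str = "seres",
    aligner: Optional[AlignerSpec] = None,
    gamma: float = 0.5,
    length_factor: float = 1.0,
    num_anchors: Optional[int] = None,
    anchor_len: int = DEFAULT_ANCHOR_LENGTH,
    min_dist: int = DEFAULT_MIN_DISTANCE,
    guide: Optional[MultipleAlignment] = None,
    seed: Optional[int] = None,
    denominator_mode: str = "co-sampled",
    extra_replicates: Optional[TypingSequence[ReplicateAlignment]] = None,
) -> SupportAnnotation:
    """End-to-end support estimation on an input alignment.

    ``method`` selects the resampling scheme (``"seres"`` or
    ``"bootstrap"``); defaults follow the standard parameterization
    (gamma 0.5, 100 replicates, floor(k/20) anchors of 5 columns with
    25-column minimum spacing).  ``extra_replicates`` pools externally
    generated replicate alignments (with original-coordinate provenance)
    into the scoring step, e.g. parametrically perturbed alignments.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if aligner is None:
        aligner = AlignerSpec()
    if method == "seres":
        reps = seres_replicates(
            input_msa,
            n_replicates,
            aligner,
            gamma=gamma,
            length_factor=length_factor,
            num_anchors=num_anchors,
            anchor_len=anchor_len,
            min_dist=min_dist,
            guide=guide,
            seed=seed,
        )
    elif method == "bootstrap":
        reps = bootstrap_replicates(input_msa, n_replicates, aligner, seed=seed)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    if extra_replicates:
        reps = list(reps) + list(extra_replicates)
    return pair_support(input_msa, reps, denominator_mode=denominator_mode)
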