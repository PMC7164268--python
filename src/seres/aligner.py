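"""Re-alignment of resampled replicates.

Support estimation re-estimates an alignment on every resampled replicate.
Production runs normally delegate to an external progressive aligner (e.g.
``mafft --auto``) through :class:`AlignerSpec`; the package also ships a
small deterministic progressive aligner (global pairwise Needleman–Wunsch
alignments star-merged around a centroid sequence) so the full pipeline and
test suite run with no external binary.

Whatever the aligner, its contract is fixed: degapping each output row must
reproduce the corresponding input sequence exactly, so residue-level
provenance composes through the re-alignment.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import GAP, MultipleAlignment, Sequence, read_fasta, write_fasta
from .unaligned_walk import UnalignedReplicate

MATCH = 1
MISMATCH = -1
GAP_PENALTY = -2


class AlignerContractError(RuntimeError):
    """The aligner altered residue content or order of an input sequence."""


class AlignerInvocationError(RuntimeError):
    """External aligner command failed; carries its stderr."""


@dataclass(frozen=True)
class AlignerSpec:
    """How to re-align a replicate.

    mode:
        ``"builtin"`` uses :func:`builtin_progressive_align`;
        ``"external"`` runs ``command_template`` through the shell with
        ``{in}``/``{out}`` placeholders for FASTA paths, e.g.
        ``"mafft --quiet {in} > {out}"``.
    """

    mode: str = "builtin"
    command_template: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("builtin", "external"):
            raise ValueError(f"unknown aligner mode {self.mode!r}")
        if self.mode == "external" and not self.command_template:
            raise ValueError("external mode needs a command template")


def needleman_wunsch(
    a: str,
    b: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP_PENALTY,
) -> tuple[str, str, int]:
    """Deterministic global pairwise alignment.

    Linear gap penalty; the DP matrix is filled anti-diagonal by
    anti-diagonal (vectorized), and the traceback resolves ties in the
    fixed order diagonal > up > left.
    """
    la, lb = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((la + 1, lb + 1), dtype=np.int64)
    H[:, 0] = gap * np.arange(la + 1)
    H[0, :] = gap * np.arange(lb + 1)
    for d in range(2, la + lb + 1):
        ilo = max(1, d - lb)
        ihi = min(la, d - 1)
        if ilo > ihi:
            continue
        rows = np.arange(ilo, ihi + 1)
        cols = d - rows
        sub = np.where(aa[rows - 1] == bb[cols - 1], match, mismatch)
        H[rows, cols] = np.maximum(
            H[rows - 1, cols - 1] + sub,
            np.maximum(H[rows - 1, cols] + gap, H[rows, cols - 1] + gap),
        )
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    while i > 0 and j > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    while i > 0:
        out_a.append(a[i - 1])
        out_b.append(GAP)
        i -= 1
    while j > 0:
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(H[la, lb])


def _pairwise_to_slots(
    aln_c: str, aln_o: str, centroid_len: int
) -> tuple[list[str], list[str]]:
    """Decompose a (centroid, other) pairwise alignment.

    Returns (per-residue characters of the other sequence aligned to each
    centroid residue, with '-' where the centroid residue aligns to a gap)
    and (insertion strings of the other sequence falling in each of the
    centroid_len + 1 inter-residue slots).
    """
    per_residue = [GAP] * centroid_len
    slots = [""] * (centroid_len + 1)
    ci = 0
    for cc, oc in zip(aln_c, aln_o):
        if cc == GAP:
            slots[ci] += oc
        else:
            per_residue[ci] = oc
            ci += 1
    return per_residue, slots


def builtin_progressive_align(seqs: list[Sequence]) -> MultipleAlignment:
    """Deterministic star alignment around a centroid sequence.

    The centroid maximizes the total pairwise Needleman–Wunsch score to all
    other sequences (ties broken by smallest id).  Each other sequence is
    aligned pairwise to the centroid, and the pairwise alignments are
    merged slot-wise: each inter-residue slot of the centroid is widened to
    the longest insertion observed there, with insertions left-justified.
    The merged result is invariant to the input row order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    n = len(seqs)
    score = np.zeros((n, n))
    pair_aln: dict[tuple[int, int], tuple[str, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            ai, aj, s = needleman_wunsch(seqs[i].residues, seqs[j].residues)
            score[i, j] = score[j, i] = s
            pair_aln[(i, j)] = (ai, aj)
    totals = score.sum(axis=1)
    centroid = min(range(n), key=lambda i: (-totals[i], seqs[i].id))
    clen = len(seqs[centroid])

    per_residue: dict[int, list[str]] = {}
    slots_by_seq: dict[int, list[str]] = {}
    slot_width = [0] * (clen + 1)
    for i in range(n):
        if i == centroid:
            continue
        lo, hi = min(i, centroid), max(i, centroid)
        a_lo, a_hi = pair_aln[(lo, hi)]
        aln_c, aln_o = (a_lo, a_hi) if centroid == lo else (a_hi, a_lo)
        pr, slots = _pairwise_to_slots(aln_c, aln_o, clen)
        per_residue[i] = pr
        slots_by_seq[i] = slots
        slot_width = [max(w, len(s)) for w, s in zip(slot_width, slots)]

    rows = []
    for i in range(n):
        parts = []
        for c in range(clen + 1):
            if i == centroid:
                ins = ""
            else:
                ins = slots_by_seq[i][c]
            parts.append(ins.ljust(slot_width[c], GAP))
            if c < clen:
                if i == centroid:
                    parts.append(seqs[centroid].residues[c])
                else:
                    parts.append(per_residue[i][c])
        rows.append("".join(parts))
    return MultipleAlignment([s.id for s in seqs], rows)


def _run_external(seqs: list[Sequence], template: str) -> MultipleAlignment:
    with tempfile.TemporaryDirectory(prefix="seres-align-") as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        write_fasta(fin, seqs)
        cmd = template.replace("{in}", shlex.quote(str(fin))).replace(
            "{out}", shlex.quote(str(fout))
        )
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0 or not fout.exists():
            raise AlignerInvocationError(
                f"aligner command failed (exit {proc.returncode}): "
                f"{proc.stderr.strip()}"
            )
        msa = read_fasta(fout, aligned=True)
    assert isinstance(msa, MultipleAlignment)
    return msa


def align_sequences(
    seqs: list[Sequence], aligner: AlignerSpec
) -> MultipleAlignment:
    """Align sequences with the configured aligner and verify its contract."""
    if aligner.mode == "builtin":
        msa = builtin_progressive_align(seqs)
    else:
        msa = _run_external(seqs, aligner.command_template)
    by_id = {s.id: s for s in seqs}
    if set(msa.ids) != set(by_id):
        raise AlignerContractError("aligner changed the set of sequence ids")
    for label, deg in zip(msa.ids, msa.degap()):
        if deg.residues != by_id[label].residues:
            raise AlignerContractError(
                f"aligner altered residues of sequence {label!r}"
            )
    # normalize row order back to the input order
    order = [msa.ids.index(s.id) for s in seqs]
    return MultipleAlignment(
        [msa.ids[i] for i in order], [msa.rows[i] for i in order]
    )


def realign_replicate(
    rep: UnalignedReplicate, aligner: AlignerSpec
) -> MultipleAlignment:
    """Re-estimate an alignment on one resampled replicate."""
    return align_sequences(rep.sequences, aligner)
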