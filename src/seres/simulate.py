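"""Synthetic sequence evolution with full homology bookkeeping.

The generator emulates a classical alignment-benchmark design: a
birth–death model tree whose branch lengths are redrawn uniformly from
(0, 1) and rescaled so the tree height hits a target *h* (expected
substitutions per site); a 1 kb root sequence evolved down the tree under
a General Time-Reversible (GTR) substitution model; and insertion/deletion
events at a rate *r_i* relative to substitutions, with indel lengths drawn
from a pluggable distribution (geometric by default).  Because every
residue carries a global column identity through insertions and deletions,
the generator knows the *true alignment* of the leaf sequences exactly,
which is what support estimates are evaluated against.

The GTR rate matrix is Q_ij = s_ij * pi_j (i != j), normalized so the
expected substitution rate at stationarity is 1 per unit branch length;
transition matrices P(t) = exp(Qt) come from a one-time symmetric
eigendecomposition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional

import dendropy
import numpy as np

from ._rng import RngLike, as_generator
from .anchors import window_anhd
from .io import GAP, MultipleAlignment, Sequence, extract_homologies

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Default GTR exchangeabilities, order (AC, AG, AT, CG, CT, GT): a mild
#: transition/transversion asymmetry.  Overridable; see docs/methods.md.
DEFAULT_GTR_RATES = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0)
#: Default stationary base frequencies (A, C, G, T), mildly AT-rich.
DEFAULT_BASE_FREQS = (0.3, 0.2, 0.2, 0.3)


@dataclass(frozen=True)
class SimulationParams:
    """Model condition for one synthetic dataset.

    n_taxa:
        Number of leaves (study conditions used 10 or 50).
    height:
        Tree height in expected substitutions per site.
    indel_prob:
        Insertion rate and deletion rate per site, each relative to the
        unit substitution rate.
    root_length:
        Root sequence length in residues (default 1000).
    gtr_rates / base_freqs:
        Six GTR exchangeabilities (AC, AG, AT, CG, CT, GT) and four
        stationary frequencies summing to 1.
    gap_length_mean:
        Mean of the default geometric indel-length distribution; ignored
        when ``gap_length_sampler`` is given.
    gap_length_sampler:
        Optional callable ``rng -> int`` drawing indel lengths >= 1.
    """

    n_taxa: int = 10
    height: float = 1.0
    indel_prob: float = 0.06
    root_length: int = 1000
    gtr_rates: tuple[float, ...] = DEFAULT_GTR_RATES
    base_freqs: tuple[float, ...] = DEFAULT_BASE_FREQS
    gap_length_mean: float = 4.0
    gap_length_sampler: Optional[Callable[[np.random.Generator], int]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not self.height > 0:
            raise ValueError("height must be positive")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.indel_prob < 0:
            raise ValueError("indel_prob must be >= 0")
        if len(self.gtr_rates) != 6 or any(r <= 0 for r in self.gtr_rates):
            raise ValueError("gtr_rates must be 6 positive exchangeabilities")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if len(freqs) != 4 or np.any(freqs <= 0):
            raise ValueError("base_freqs must be 4 positive frequencies")
        if not np.isclose(freqs.sum(), 1.0):
            raise ValueError("base_freqs must sum to 1")

    def draw_gap_length(self, rng: np.random.Generator) -> int:
        if self.gap_length_sampler is not None:
            return int(self.gap_length_sampler(rng))
        return int(rng.geometric(1.0 / self.gap_length_mean))


@dataclass
class TrueAlignmentBundle:
    """A model tree, the true leaf alignment, and the unaligned sequences."""

    tree: dendropy.Tree
    true_msa: MultipleAlignment
    unaligned: list[Sequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.unaligned:
            self.unaligned = self.true_msa.degap()


class GTRModel:
    """GTR rate matrix with cached spectral decomposition."""

    def __init__(
        self,
        rates: tuple[float, ...] = DEFAULT_GTR_RATES,
        freqs: tuple[float, ...] = DEFAULT_BASE_FREQS,
    ):
        pi = np.asarray(freqs, dtype=float)
        if np.any(pi <= 0):
            raise ValueError("degenerate GTR: zero base frequency")
        s = np.zeros((4, 4))
        ac, ag, at, cg, ct, gt = rates
        s[0, 1] = s[1, 0] = ac
        s[0, 2] = s[2, 0] = ag
        s[0, 3] = s[3, 0] = at
        s[1, 2] = s[2, 1] = cg
        s[1, 3] = s[3, 1] = ct
        s[2, 3] = s[3, 2] = gt
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalize: expected rate at stationarity = 1 per unit time
        mu = -(pi * np.diag(q)).sum()
        q /= mu
        self.pi = pi
        self.Q = q
        # reversible Q is similar to the symmetric S = D^1/2 Q D^-1/2,
        # so P(t) = D^-1/2 V exp(Wt) V^T D^1/2 with S = V W V^T
        sqrt_pi = np.sqrt(pi)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        w, v = np.linalg.eigh((sym + sym.T) / 2.0)
        self._w = w
        self._right = v / sqrt_pi[:, None]
        self._left = v.T * sqrt_pi[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        p = (self._right * np.exp(self._w * t)[None, :]) @ self._left
        return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum(
            axis=1, keepdims=True
        )


def sample_tree(
    n_taxa: int, height: float, seed: RngLike = None
) -> dendropy.Tree:
    """A birth–death (pure-birth) topology with redrawn, rescaled branches.

    Branch lengths are redrawn uniformly from (0, 1) and then all scaled by
    ``height / h0`` so the maximum root-to-leaf path equals ``height``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = as_generator(seed)
    py_rng = random.Random(int(rng.integers(2**31)))
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=py_rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.uniform(0.0, 1.0))
        else:
            edge.length = 0.0
    h0 = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    factor = height / h0
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length *= factor
    return tree


class _MasterOrder:
    """Global left-to-right order of true-alignment columns."""

    def __init__(self, n: int):
        self.cols: list[int] = list(range(n))
        self.next_id = n

    def new_columns(
        self, count: int, after: Optional[int], before: Optional[int]
    ) -> list[int]:
        """Allocate ``count`` fresh column ids between two existing ones."""
        ids = list(range(self.next_id, self.next_id + count))
        self.next_id += count
        if after is not None:
            pos = self.cols.index(after) + 1
        elif before is not None:
            pos = self.cols.index(before)
        else:
            pos = len(self.cols)
        self.cols[pos:pos] = ids
        return ids


def _evolve_branch(
    tokens: list[tuple[int, int]],
    t: float,
    params: SimulationParams,
    model: GTRModel,
    master: _MasterOrder,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Evolve one branch: indel events in time order, then substitutions.

    ``tokens`` are (column id, base index) pairs.  Inherited residues
    substitute over the full branch length; residues inserted at event time
    te are drawn from the stationary distribution and substitute over the
    remaining ``t - te``.
    """
    work: list[list] = [[cid, base, 0.0] for cid, base in tokens]
    n_events = (
        rng.poisson(2.0 * params.indel_prob * len(tokens) * t)
        if params.indel_prob > 0
        else 0
    )
    for te in np.sort(rng.uniform(0.0, t, size=n_events)):
        length = params.draw_gap_length(rng)
        if rng.random() < 0.5:  # insertion
            p = int(rng.integers(len(work) + 1))
            after = work[p - 1][0] if p > 0 else None
            before = work[p][0] if p < len(work) else None
            ids = master.new_columns(length, after, before)
            bases = rng.choice(4, size=length, p=model.pi)
            work[p:p] = [
                [cid, int(b), float(te)] for cid, b in zip(ids, bases)
            ]
        else:  # deletion
            if not work:
                continue
            p = int(rng.integers(len(work)))
            del work[p : p + length]

    if not work:
        return []
    # substitutions, grouped by identical residual time
    by_birth: dict[float, list[int]] = {}
    for idx, (_, _, birth) in enumerate(work):
        by_birth.setdefault(birth, []).append(idx)
    for birth, idxs in by_birth.items():
        p = model.transition_matrix(t - birth)
        states = np.array([work[i][1] for i in idxs])
        u = rng.random(len(idxs))
        cdf = np.cumsum(p, axis=1)
        new_states = (u[:, None] > cdf[states]).sum(axis=1)
        for i, s in zip(idxs, new_states):
            work[i][1] = int(s)
    return [(cid, base) for cid, base, _ in work]


def evolve_sequences(
    tree: dendropy.Tree,
    params: SimulationParams,
    seed: RngLike = None,
) -> TrueAlignmentBundle:
    """Evolve sequences down a model tree, tracking the true alignment."""
    rng = as_generator(seed if seed is not None else params.seed)
    model = GTRModel(params.gtr_rates, params.base_freqs)
    master = _MasterOrder(params.root_length)
    root_bases = rng.choice(4, size=params.root_length, p=model.pi)
    root_tokens = [(i, int(b)) for i, b in enumerate(root_bases)]

    tokens_at: dict[dendropy.Node, list[tuple[int, int]]] = {
        tree.seed_node: root_tokens
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_tokens = tokens_at[node.parent_node]
        tokens_at[node] = _evolve_branch(
            parent_tokens, node.edge.length or 0.0, params, model, master, rng
        )

    leaves = sorted(
        tree.leaf_node_iter(), key=lambda nd: nd.taxon.label
    )
    leaf_maps = []
    present: set[int] = set()
    for leaf in leaves:
        cmap = {cid: BASES[b] for cid, b in tokens_at[leaf]}
        leaf_maps.append(cmap)
        present.update(cmap)
    columns = [c for c in master.cols if c in present]
    ids = [leaf.taxon.label for leaf in leaves]
    rows = [
        "".join(cmap.get(c, GAP) for c in columns) for cmap in leaf_maps
    ]
    msa = MultipleAlignment(ids, rows)
    return TrueAlignmentBundle(tree=tree, true_msa=msa)


def simulate_dataset(params: SimulationParams) -> TrueAlignmentBundle:
    """Draw a model tree and evolve a dataset in one call."""
    rng = as_generator(params.seed)
    tree = sample_tree(params.n_taxa, params.height, rng)
    return evolve_sequences(tree, params, seed=rng)


def summary_stats(bundle: TrueAlignmentBundle) -> tuple[float, float, int]:
    """(ANHD, gappiness, true alignment length) of a simulated dataset.

    ANHD is the mean pairwise normalized Hamming distance over true
    alignment rows with indels counted as mismatches; gappiness is the
    fraction of alignment cells that are gaps.
    """
    msa = bundle.true_msa
    anhd = window_anhd(msa, 0, msa.k)
    gaps = sum(row.count(GAP) for row in msa.rows)
    gappiness = gaps / (msa.n * msa.k)
    return anhd, gappiness, msa.k


def pair_error_rates(
    true_msa: MultipleAlignment, est_msa: MultipleAlignment
) -> tuple[float, float]:
    """(SP-FN, SP-FP): the proportion of true-alignment homologies missing
    from the estimated alignment, and of estimated-alignment homologies
    absent from the true alignment."""
    true_seqs = {s.id: s.residues for s in true_msa.degap()}
    est_seqs = {s.id: s.residues for s in est_msa.degap()}
    if true_seqs != est_seqs:
        raise ValueError("alignments are not over identical sequences")
    true_pairs = extract_homologies(true_msa)
    est_pairs = extract_homologies(est_msa)
    sp_fn = len(true_pairs - est_pairs) / len(true_pairs) if true_pairs else 0.0
    sp_fp = len(est_pairs - true_pairs) / len(est_pairs) if est_pairs else 0.0
    return sp_fn, sp_fp
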