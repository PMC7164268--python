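# Methods

## The resampling model

### Walks on aligned sites

The aligned-mode walk lives on the column indices {0, …, k−1} of a fixed
alignment. A start site and travel direction are drawn uniformly; each
step emits the current site, then chooses the next direction — forced
inward at the two boundary sites, reversed with probability γ elsewhere —
and moves one site. The walk stops after emitting exactly k sites, so
every replicate conserves the input length.

Step order is emit → flip → move, with the boundary reversal certain and
overriding the γ draw. This makes a boundary column emitted exactly once
per visit and keeps the walk inside [0, k) for every γ, including γ = 1.
The two γ = 0 walks started at the ends are the Heads-or-Tails pair
(identity and column reversal). k = 1 is handled as a special case that
emits column 0 repeatedly, since the two boundary rules coincide there.

Occupancy is not exactly uniform: the certain boundary reversal gives the
two end sites roughly half the stationary weight of interior sites (the
reflecting-walk degree effect), and a uniform start relaxes toward that
stationary profile over a boundary layer of order √k sites, which are
transiently oversampled by up to ~10% at k = 50. Beyond that layer the
occupancy is uniform to within Monte-Carlo noise; the test suite checks
±10% for sites at least k/10 from either end and separately compares the
full empirical profile against the exact first-order chain computed by
dynamic programming.

### Walks on unaligned sequences

Unaligned sequences have no shared coordinate system, so the walk is
synchronized through anchors estimated on a guide alignment (by default
the input alignment itself):

* **Similarity measure.** ANHD over a column window: the mean over all
  C(n,2) sequence pairs of the fraction of mismatching columns, with any
  gap comparison — including gap-vs-gap — counted as a mismatch. The
  gap-gap convention matters only outside anchor windows, which are
  gap-free by construction.
* **Anchor selection.** Candidates are all fully gap-free windows of the
  anchor length; they are ranked by ascending ANHD (ties to the leftmost
  start) and accepted greedily under an edge-to-edge minimum spacing.
  Requesting more anchors than feasibility allows yields the feasible
  maximum and a warning. Gap-free windows are required so each anchor
  boundary cuts every sequence at a single well-defined unaligned offset.
* **Barriers.** Each anchor boundary column c maps, per sequence, to the
  count of that row's non-gap cells left of c. Together with the trivial
  all-zeros and all-lengths barriers these form a non-decreasing matrix of
  cut points; duplicate barriers are dropped.

The walk starts at a uniform barrier (forced inward at the trivial ones)
and traverses to a neighboring barrier, appending, for every sequence, the
residues between its two cut points — natural order moving right, reversed
moving left. The global orientation flip is what preserves residue
adjacency across traversal boundaries while keeping all sequences on the
same traversal schedule. After each arrival the direction reverses with
certainty at trivial barriers, else with probability γ. The walk stops at
the first arrival at which the longest resampled sequence has reached
`length_factor` × the longest input length (default 1.0, mirroring the
aligned walk's length conservation; the parameter has no canonical
default). Termination is only checked at barrier arrivals — segments are
atomic — and additionally waits until every resampled sequence is
non-empty, because downstream re-alignment requires non-empty rows; this
wait is skipped when γ = 1, where the walk can be pinned between two
barriers forever. Anchor interiors are ordinary segments: anchors serve
synchronization only.

## Support estimation

Given an input alignment A, replicates of its unaligned sequences are
re-aligned and each residue-pair homology of A is scored by its replicate
frequency. A replicate supports a homology when at least one column of its
re-estimated alignment co-aligns occurrences of the two original residues;
the binary rule is needed because a walk can emit a residue more than
once, and it reduces to classical GUIDANCE scoring when every residue is
sampled exactly once. The default denominator counts only replicates in
which both residues were sampled at all ("co-sampled"), so boundary
residues the walk visits less often are not deflated; a total-replicate
denominator is available. A pair whose co-sampled denominator is zero is
reported as 0.0 (not NaN) to keep all scores on the unit interval.

Re-alignment goes through a fixed contract — degapping each output row
must reproduce the input sequences — enforced for both the external-command
path (e.g. `mafft --quiet {in} > {out}`) and the built-in aligner. The
built-in aligner is a deterministic star alignment: global pairwise
Needleman–Wunsch (match +1, mismatch −1, gap −2, traceback ties resolved
diagonal > up > left) around the centroid sequence (maximum total pairwise
score, ties to the smallest id), merged slot-wise so the result is
invariant to input row order. It exists so the full pipeline is
self-contained and deterministic; it is a simple aligner, not a MAFFT
replacement, and production use should pass an external aligner command.

The classical comparator (`method="bootstrap"`) resamples input-alignment
columns i.i.d. with replacement, degaps the resampled rows (provenance
flows through the input alignment's cells), and re-aligns them identically
— so the resampling scheme is the only difference between the two
pipelines. Externally generated replicate alignments with
original-coordinate provenance can be pooled into scoring via
`extra_replicates`, mirroring compositions with parametric perturbation
methods.

## Evaluation

Support annotates homologies of the *estimated* alignment, so true-only
homologies are out of scope. At threshold t (positive call at score ≥ t),
TP/FP/FN/TN follow the standard set definitions; sweeping the distinct
score values yields ROC and PR curves. ROC-AUC uses the trapezoid rule;
PR-AUC uses the right-step sum consistent with average precision.
Precision at tp+fp = 0 is defined as 1.0; a single-class score set
produces a degenerate ROC curve with a warning. Multi-dataset aggregation
offers both pooled (concatenated homologies, one sweep) and per-dataset
mean AUC, since either reading of "aggregate" is defensible.

## The simulator

The generator emulates a standard alignment-benchmark design: a pure-birth
topology (birth rate 1, death rate 0 — topology shape is irrelevant
because branch lengths are immediately redrawn) with branch lengths
U(0, 1) rescaled by h/h₀ so the maximum root-to-leaf path equals the
target height h; a root sequence (default 1000 residues, 300 in the
scaled-down study conditions) drawn from the GTR stationary distribution;
GTR substitutions via P(t) = exp(Qt) from a one-time symmetric
eigendecomposition, with Q normalized to unit expected rate; and indel
events at rate `indel_prob` per site each for insertions and deletions,
relative to substitutions.

Indel kinematics per branch: the event count is Poisson(2·r·L₀·t) with L₀
the branch-start length (the rate is not updated between events within a
branch — a simplification that is accurate at these event densities);
events are processed in time order; insertion positions and deletion start
positions are uniform; lengths come from the gap-length distribution.
Inserted residues are drawn from the stationary distribution and
substitute over the remaining branch time. Every residue carries a global
column identity, so the true alignment of the leaves is known exactly and
degapping it reproduces the unaligned sequences.

Two parameter sets are deliberately package-chosen because no canonical
values are available: the GTR exchangeabilities (default
AC:AG:AT:CG:CT:GT = 1:2:1:1:2:1, a mild transition bias) and base
frequencies (0.3, 0.2, 0.2, 0.3), and the gap-length distribution
(geometric with mean 4, pluggable via `gap_length_sampler`). Both are
overridable; none of the package's conclusions depend on the specific
values.

What the generator does *not* emulate: rate heterogeneity across sites,
codon/protein models, sequence motifs or secondary-structure constraints,
and empirical-alignment gap structure. Passing tests therefore demonstrate
the resampling and scoring machinery under a clean homogeneous model, not
performance on curated rRNA benchmarks.

## Study conditions used by tests and the acceptance script

The directional comparison (SERES vs bootstrap support) runs on five
10-taxon datasets with 300 bp roots, height 0.5 and indel rate 0.06.
Under this package's simulator those settings give pairwise ANHD ≈ 0.6 —
the divergent end of the regime where support estimation is hard but the
estimated alignment still contains a substantial share of true homologies
(SP-FN ≈ 0.4 with the built-in aligner) — and leave several feasible
anchors per dataset. 16 replicates per method per dataset are enough to
rank the two schemes; the full-scale parameterization (100 replicates,
1 kb roots, MAFFT) is the package default for real use.

## Numerical and degenerate-input choices

* Coordinates 0-based, intervals half-open, everywhere.
* Gap symbol `-`; `.` normalized on read; residues uppercased; IUPAC
  ambiguity codes accepted by I/O and treated as ordinary (mismatching)
  characters in similarity computations.
* Duplicate barrier rows are dropped; zero-length segments are legal.
* `needleman_wunsch` fills the DP matrix anti-diagonally (vectorized) and
  resolves traceback ties in a fixed order, so alignments are
  reproducible across platforms.
* All randomness flows from numpy Generators; a master seed spawns one
  child stream per replicate index (`SeedSequence(master, spawn_key=(r,))`),
  so replicate r is identical whether 10 or 100 replicates are requested.

## Known limitations

* The built-in star aligner has no affine gaps and no iterative
  refinement; its alignments are noticeably worse than MAFFT's, which
  depresses absolute support quality (but affects both resampling schemes
  equally).
* Support for residue-indel pairs is not implemented; scoring covers
  residue-residue homologies only.
* Anchor discovery requires a guide alignment; there is no alignment-free
  (k-mer) anchor mode.
* Walk and simulator loops are pure Python/numpy and sized for datasets of
  tens of taxa and kilobase-scale sequences, not genome-scale inputs.
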