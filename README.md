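# seres

Sequential-resampling (SERES) random walks for multiple sequence alignment
support estimation.

## The problem

Non-parametric support estimation — the standard bootstrap above all —
resamples observations i.i.d. For biomolecular sequences that assumption is
wrong in an essential way: neighboring residues depend on each other
through biochemical function, indel history, recombination, and more. The
Heads-or-Tails idea (analysis should be repeatable reading an alignment
left-to-right or right-to-left) respects that dependence but yields only
two replicates.

SERES generalizes both: a random walk along the sequence emits positions
one at a time, reversing direction with probability γ (and with certainty
at the sequence ends). Every replicate satisfies the **neighbor
preservation property** — any two adjacent residues of a resampled
sequence were adjacent in the original — while arbitrarily many distinct
replicates can be drawn. γ = 0 from the two ends recovers exactly the
Heads-or-Tails pair; γ = 0.5 makes each step an independent coin flip.

Two modes:

* **Aligned.** The walk runs over the k columns of a fixed alignment and
  stops after emitting exactly k columns.
* **Unaligned.** Sequences are synchronized through *anchors*: gap-free,
  high-similarity windows of a guide alignment, scored by average
  normalized Hamming distance (ANHD, indels count as mismatches). Anchor
  boundaries become per-sequence *barriers*, the walk moves from barrier
  to neighboring barrier emitting the residues in between (reversed when
  moving left), and stops once the longest resampled sequence reaches
  `length_factor` × the longest input length.

The downstream application is GUIDANCE-style alignment support: resample
the unaligned sequences of an input alignment *A*, re-align every
replicate (MAFFT externally, or a built-in deterministic progressive
aligner), and score each residue-pair homology of *A* by the fraction of
replicates whose re-estimated alignment recovers it. Scores are evaluated
against a true alignment with ROC and PR curves over the estimated
alignment's homologies (TPR = |TP|/(|TP|+|FN|), FPR = |FP|/(|FP|+|TN|),
precision = |TP|/(|TP|+|FP|), positive call at support ≥ threshold).

A built-in simulator (birth–death trees with U(0,1) branch lengths
rescaled to a target height, GTR substitutions, indel events with a
pluggable length distribution, exact true-alignment bookkeeping) makes the
whole pipeline testable end to end without any external data.

## Worked example

```python
from seres import *

params = SimulationParams(n_taxa=6, height=0.5, indel_prob=0.06,
                          root_length=120, seed=11)
bundle = simulate_dataset(params)
anhd, gappiness, k = summary_stats(bundle)
print(f"ANHD={anhd:.3f} gappiness={gappiness:.3f} true_len={k}")

est = align_sequences(bundle.unaligned, AlignerSpec())
sp_fn, sp_fp = pair_error_rates(bundle.true_msa, est)
print(f"estimated alignment: k={est.k} SP-FN={sp_fn:.3f} SP-FP={sp_fp:.3f}")

ann = run_support_pipeline(est, n_replicates=20, method="seres", seed=3)
print(f"scored {len(ann.pair_scores)} homologies, "
      f"ROC-AUC={roc_auc(bundle.true_msa, est, ann):.3f} "
      f"PR-AUC={pr_auc(bundle.true_msa, est, ann):.3f}")
```

prints

```
ANHD=0.483 gappiness=0.150 true_len=147
estimated alignment: k=151 SP-FN=0.220 SP-FP=0.210
scored 1706 homologies, ROC-AUC=0.702 PR-AUC=0.865
```

The simulated condition is moderately divergent (pairwise ANHD 0.48); the
built-in aligner recovers it imperfectly (22% of true homologies missed,
21% of estimated homologies spurious), and resampling-based support
separates correct from spurious homologies well above chance (ROC-AUC
0.70 — a random scorer gives 0.5).

The same pipeline is available from a shell:

```sh
seres simulate --taxa 10 --height 0.5 --root-length 300 --seed 1 --out-dir sim/
seres support --msa sim/true.fasta --replicates 100 --seed 1 --scores scores.tsv
seres evaluate --true sim/true.fasta --est sim/true.fasta \
    --scores scores.tsv --out metrics.json
```

Defaults follow the method's standard parameterization: γ = 0.5,
100 replicates, ⌊k/20⌋ anchors of 5 columns with a 25-column minimum
spacing. `--aligner-cmd "mafft --quiet {in} > {out}"` switches replicate
re-estimation to MAFFT.

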