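"""Sequence-evolution simulator: trees, substitutions, indels, statistics."""

import numpy as np
import pytest
from scipy.linalg import expm

from seres import (
    MultipleAlignment,
    SimulationParams,
    evolve_sequences,
    extract_homologies,
    pair_error_rates,
    sample_tree,
    simulate_dataset,
    summary_stats,
)
from seres.simulate import GTRModel


class TestSampleTree:
    def test_leaf_count_and_height(self):
        for n, h in ((10, 1.0), (5, 0.4), (12, 4.3)):
            tree = sample_tree(n, h, seed=3)
            leaves = list(tree.leaf_node_iter())
            assert len(leaves) == n
            height = max(leaf.distance_from_root() for leaf in leaves)
            assert height == pytest.approx(h, abs=1e-9)

    def test_rescaling_scales_every_branch(self):
        t1 = sample_tree(6, 1.0, seed=5)
        t2 = sample_tree(6, 2.0, seed=5)
        b1 = sorted(
            e.length for e in t1.preorder_edge_iter() if e.tail_node is not None
        )
        b2 = sorted(
            e.length for e in t2.preorder_edge_iter() if e.tail_node is not None
        )
        assert np.allclose(np.array(b2), 2 * np.array(b1))


class TestGTRModel:
    def test_transition_matrix_properties(self):
        m = GTRModel()
        for t in (0.01, 0.5, 3.0):
            p = m.transition_matrix(t)
            assert np.allclose(p.sum(axis=1), 1.0)
            assert np.all(p >= 0)
        assert np.allclose(m.transition_matrix(0.0), np.eye(4), atol=1e-12)

    def test_matches_scipy_expm(self):
        m = GTRModel((1.3, 2.9, 0.8, 1.1, 3.3, 1.0), (0.35, 0.15, 0.2, 0.3))
        for t in (0.1, 0.7, 2.0):
            assert np.allclose(m.transition_matrix(t), expm(m.Q * t), atol=1e-10)

    def test_stationarity_and_unit_rate(self):
        m = GTRModel()
        assert np.allclose(m.pi @ m.Q, 0.0, atol=1e-12)
        assert -(m.pi * np.diag(m.Q)).sum() == pytest.approx(1.0)

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            GTRModel(freqs=(0.5, 0.5, 0.0, 0.0))


class TestEvolve:
    def test_no_indels_keeps_root_length(self):
        params = SimulationParams(
            n_taxa=6, height=0.5, indel_prob=0.0, root_length=120, seed=2
        )
        bundle = simulate_dataset(params)
        anhd, gappiness, k = summary_stats(bundle)
        assert gappiness == 0.0
        assert k == 120
        assert all(len(s) == 120 for s in bundle.unaligned)

    def test_vanishing_height_gives_identical_sequences(self):
        params = SimulationParams(
            n_taxa=5, height=1e-9, indel_prob=0.05, root_length=100, seed=4
        )
        bundle = simulate_dataset(params)
        anhd, _, _ = summary_stats(bundle)
        assert anhd == pytest.approx(0.0, abs=1e-6)
        assert len({s.residues for s in bundle.unaligned}) == 1

    def test_degap_invariant(self, small_bundle):
        assert [s.residues for s in small_bundle.true_msa.degap()] == [
            s.residues for s in small_bundle.unaligned
        ]

    def test_single_branch_substitutions_match_expected_rate(self):
        """Mismatch fraction on a two-leaf tree agrees with the closed form
        q(t) = 1 - sum_i pi_i P_ii(t) within 3 sigma, averaged over repeats."""
        model = GTRModel()
        L = 1500
        mismatches = []
        for seed in range(10):
            tree = sample_tree(2, 0.4, seed=seed)
            leaves = list(tree.leaf_node_iter())
            t_total = sum(leaf.distance_from_root() for leaf in leaves)
            params = SimulationParams(
                n_taxa=2, height=0.4, indel_prob=0.0, root_length=L, seed=seed
            )
            bundle = evolve_sequences(tree, params, seed=seed)
            a, b = (s.residues for s in bundle.unaligned)
            observed = sum(x != y for x, y in zip(a, b)) / L
            p = expm(model.Q * t_total)
            expected = 1.0 - float((model.pi * np.diag(p)).sum())
            sigma = np.sqrt(expected * (1 - expected) / L)
            mismatches.append((observed - expected) / sigma)
        assert abs(np.mean(mismatches)) < 3.0 / np.sqrt(10)

    def test_determinism_and_seed_sensitivity(self):
        p1 = SimulationParams(n_taxa=5, height=0.5, root_length=80, seed=31)
        p2 = SimulationParams(n_taxa=5, height=0.5, root_length=80, seed=32)
        b1 = simulate_dataset(p1)
        b1b = simulate_dataset(p1)
        b2 = simulate_dataset(p2)
        assert b1.true_msa == b1b.true_msa
        assert b1.true_msa != b2.true_msa

    def test_anhd_increases_with_height(self):
        means = []
        for h in (0.1, 0.5, 2.0):
            vals = [
                summary_stats(
                    simulate_dataset(
                        SimulationParams(
                            n_taxa=6, height=h, indel_prob=0.02,
                            root_length=150, seed=50 + s,
                        )
                    )
                )[0]
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestSummaryStats:
    def test_hand_case(self):
        bundle_msa = MultipleAlignment(["a", "b"], ["AC-T", "ACGT"])
        from seres.simulate import TrueAlignmentBundle

        bundle = TrueAlignmentBundle(tree=None, true_msa=bundle_msa)
        anhd, gappiness, k = summary_stats(bundle)
        assert gappiness == pytest.approx(1 / 8)
        assert anhd == pytest.approx(0.25)
        assert k == 4

    def test_recompute_from_disk(self, small_bundle, tmp_path):
        from seres import read_fasta, write_fasta

        write_fasta(tmp_path / "true.fasta", small_bundle.true_msa)
        again = read_fasta(tmp_path / "true.fasta", aligned=True)
        from seres.simulate import TrueAlignmentBundle

        re_bundle = TrueAlignmentBundle(tree=None, true_msa=again)
        assert summary_stats(re_bundle) == summary_stats(small_bundle)


class TestPairErrorRates:
    def test_identical_alignments_zero_error(self):
        msa = MultipleAlignment(["a", "b"], ["AC-T", "ACGT"])
        assert pair_error_rates(msa, msa) == (0.0, 0.0)

    def test_disjoint_homologies_full_error(self):
        true_msa = MultipleAlignment(["a", "b"], ["AC", "AC"])
        est_msa = MultipleAlignment(["a", "b"], ["AC-", "-AC"])
        assert pair_error_rates(true_msa, est_msa) == (1.0, 1.0)

    def test_three_sequence_toy_matches_set_brute_force(self, rng):
        true_msa = MultipleAlignment(
            ["a", "b", "c"], ["ACG-T", "AC-GT", "A-CGT"]
        )
        est_msa = MultipleAlignment(
            ["a", "b", "c"], ["ACGT-", "ACG-T", "ACG-T"]
        )
        sp_fn, sp_fp = pair_error_rates(true_msa, est_msa)
        tp_set = extract_homologies(true_msa)
        ep_set = extract_homologies(est_msa)
        assert sp_fn == pytest.approx(len(tp_set - ep_set) / len(tp_set))
        assert sp_fp == pytest.approx(len(ep_set - tp_set) / len(ep_set))

    def test_different_sequences_rejected(self):
        m1 = MultipleAlignment(["a", "b"], ["ACGT", "ACGT"])
        m2 = MultipleAlignment(["a", "b"], ["ACGA", "ACGT"])
        with pytest.raises(ValueError):
            pair_error_rates(m1, m2)
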