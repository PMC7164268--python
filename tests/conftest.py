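"""Shared fixtures: random alignments and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from seres import MultipleAlignment, Sequence, SimulationParams, simulate_dataset

BASES = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n: int | None = None,
    k: int | None = None,
    gap_prob: float = 0.2,
) -> MultipleAlignment:
    """A random alignment in which every row keeps at least one residue."""
    n = int(rng.integers(2, 6)) if n is None else n
    k = int(rng.integers(2, 30)) if k is None else k
    rows = []
    for i in range(n):
        while True:
            cells = [
                "-" if rng.random() < gap_prob else BASES[rng.integers(4)]
                for _ in range(k)
            ]
            if any(c != "-" for c in cells):
                break
        rows.append("".join(cells))
    return MultipleAlignment([f"s{i}" for i in range(n)], rows)


def random_sequences(
    rng: np.random.Generator, n: int, min_len: int = 5, max_len: int = 20
) -> list[Sequence]:
    return [
        Sequence(
            f"s{i}",
            "".join(
                BASES[j] for j in rng.integers(4, size=rng.integers(min_len, max_len + 1))
            ),
        )
        for i in range(n)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated dataset shared by read-only tests."""
    params = SimulationParams(
        n_taxa=8, height=0.5, indel_prob=0.05, root_length=200, seed=11
    )
    return simulate_dataset(params)
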