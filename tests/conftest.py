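from __future__ import annotations

import numpy as np
import pytest

from coevosim.alignment import ALPHABET, AMINO_ACIDS, Alignment
from coevosim.simulate import SimulationConfig, evolve, random_disjoint_pairs


def random_alignment(
    rng: np.random.Generator, n_seq: int, n_pos: int, n_symbols: int = 20
) -> Alignment:
    rows = rng.integers(0, n_symbols, size=(n_seq, n_pos), dtype=np.uint8)
    return Alignment([f"s{i}" for i in range(n_seq)], rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def toy_aln() -> Alignment:
    return Alignment.from_sequences(
        ["a", "b", "c", "d"],
        ["ACDEF", "ACDEG", "HCDEF", "HKDEF"],
    )


def small_simulation(seed: int, **overrides):
    """A small seeded evolution run used across tests.

    60 positions, 45 lineages (3 levels), 6 covarion pairs, 3 recombination
    zones — big enough for detectors to see signal, small enough to run in
    well under a second.
    """
    pair_rng = np.random.default_rng(10_000 + seed)
    defaults = dict(
        n_pos=60,
        branching=(3, 2, 4),
        cycles_per_level=5,
        mutation_prob=0.02,
        covarion_pairs=random_disjoint_pairs(60, 6, pair_rng),
        covarion_mut_prob=0.2,
        crossover_points=(20, 40),
        recombination_prob=0.1,
        n_seq=40,
    )
    defaults.update(overrides)
    cfg = SimulationConfig(**defaults)
    return evolve(cfg, seed=seed)


def pdb_text(coords: list[tuple[float, float, float]], chain: str = "A") -> str:
    """Minimal single-atom-per-residue PDB text for contact-map tests."""
    lines = []
    for k, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {k:5d}  CA  ALA {chain}{k:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
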