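"""Shared fixtures: small synthetic panels and read pools."""

from __future__ import annotations

import numpy as np
import pytest

import copromito as cp


@pytest.fixture(scope="session")
def two_genome_panel() -> list[cp.ReferenceGenome]:
    """Two circular 2-kb genomes at 8% divergence."""
    return cp.generate_panel(seed=101, n_genomes=2, length=2000, divergence=0.08)


@pytest.fixture(scope="session")
def single_genome() -> cp.ReferenceGenome:
    return cp.generate_panel(seed=55, n_genomes=1, length=2000, divergence=0.0)[0]


@pytest.fixture(scope="session")
def clean_pool(two_genome_panel) -> cp.ReadPool:
    """Damage-free, error-free 70/30 pool from the two-genome panel."""
    return cp.simulate_reads(
        two_genome_panel, [0.7, 0.3], total=3000, damage=cp.DamageModel(), seed=7
    )


def mutate(sequence: str, rate: float, seed: int) -> str:
    """Independent per-site substitution at the given rate (test helper)."""
    rng = np.random.default_rng(seed)
    out = list(sequence)
    for i in np.nonzero(rng.random(len(out)) < rate)[0]:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)
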