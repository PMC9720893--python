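"""Shared fixtures: toy reads, random collections, and the default simulation."""

from __future__ import annotations

import numpy as np
import pytest

from duplexsig import (
    ReadCollection,
    SimulationConfig,
    SmallRNARead,
    classify_end_distances,
    find_duplexes,
    simulate_dataset,
)

BASES = "ACGT"


def random_collection(
    rng: np.random.Generator,
    n_reads: int,
    min_len: int = 15,
    max_len: int = 30,
    label: str = "",
) -> ReadCollection:
    """Random reads of random lengths; duplexes arise only by chance."""
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
        reads.append(SmallRNARead(f"{label}r{i}", seq))
    return ReadCollection(reads, source_label=label)


@pytest.fixture(scope="session")
def default_sim():
    """The full default simulation: 20,000 reads, 797 refs, 1,365 duplexes."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_sim_classified(default_sim):
    """Detected duplexes of the default simulation with their distances."""
    duplexes = find_duplexes(default_sim.file_a, default_sim.file_b)
    return [(d, classify_end_distances(d)) for d in duplexes]


@pytest.fixture
def small_sim():
    """A 200-read simulation with a three-class distance spec."""
    return simulate_dataset(
        SimulationConfig(
            n_total_reads=200,
            n_duplex_refs=20,
            distance_spec=[(-2, -3, 12), (0, 0, 10), (1, 2, 8)],
            seed=3,
        )
    )
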