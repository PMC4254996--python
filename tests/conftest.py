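"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from hairpin_evol.alignment_io import (
    MultipleAlignment,
    Role,
    SequenceRecord,
)
from hairpin_evol.hairpin_fold import HairpinPartition, can_pair
from hairpin_evol.synthetic_data import SimulationConfig, simulate

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def brute_force_max_pairs(seq: str, min_loop: int = 3, wobble: bool = True) -> int:
    """Exhaustive enumeration of every nested pairing — the folding oracle.

    Exponential, intended for sequences of length <= 12; shares nothing
    with the dynamic programme it checks.
    """

    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        candidates = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[k], wobble):
                candidates.append(1 + best(i + 1, k - 1) + best(k + 1, j))
        return max(candidates)

    return best(0, len(seq) - 1)


def make_alignment(rows: dict[str, str], role: Role = Role.INGROUP) -> MultipleAlignment:
    return MultipleAlignment(
        tuple(SequenceRecord.from_raw(k, v, role) for k, v in rows.items())
    )


@pytest.fixture
def toy_alignment() -> MultipleAlignment:
    """Three rows, columns: monomorphic / singleton / singleton."""
    return make_alignment({"s1": "ACG", "s2": "ACA", "s3": "ATA"})


@pytest.fixture(scope="session")
def study_partition() -> HairpinPartition:
    """The 73/66/75 split of a 214-column hairpin alignment."""
    return HairpinPartition.fixed(214, arm5_end=73, loop_end=139)


@pytest.fixture(scope="session")
def simulated_default():
    """One study-like simulated dataset (45 taxa, default constraint)."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def simulated_with_outgroup():
    return simulate(SimulationConfig(seed=23, n_outgroups=1))
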