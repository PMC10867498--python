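import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from geminate_clock import (
    Alignment,
    GroupPartition,
    LocusConfig,
    SequenceRecord,
    SimulationConfig,
    simulate_geminate,
)


def make_alignment(seqs, locus="test", ids=None):
    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    return Alignment(locus, [SequenceRecord(i, s) for i, s in zip(ids, seqs)])


@pytest.fixture
def small_alignment():
    return make_alignment(["ACGTACGTAC", "ACGTACGTAC", "ACGAACGTAC", "TCGAACGTAC"])


@pytest.fixture
def two_group_partition():
    return GroupPartition(
        {
            "s1": ("west", "west"),
            "s2": ("west", "west"),
            "s3": ("east", "east"),
            "s4": ("east", "east"),
        }
    )


@pytest.fixture(scope="session")
def geminate_dataset():
    """One COI-like simulated geminate dataset reused across tests."""
    cfg = SimulationConfig(
        loci=(LocusConfig("COI", 658, 0.049),),
        n_per_clade=6,
        intra_clade_theta=0.005,
        seed=7,
    )
    return simulate_geminate(cfg)
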