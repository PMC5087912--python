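import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture()
def tiny_genome():
    """Two short chromosomes with one forward and one reverse motif match."""
    from pipscan import GenomeSequence

    # chr1 carries TGATGGCGT (forward match) at offset 4;
    # chr2 carries ACGCCTTCA (reverse-complement match) at offset 6
    return GenomeSequence(
        {
            "chr1": "ACGT" + "TGATGGCGT" + "CCCGGGAAATTT",
            "chr2": "AATTCC" + "ACGCCTTCA" + "GG",
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """A small-but-complete simulated study reused by several test modules."""
    from pipscan import SimulationParams, simulate_study

    params = SimulationParams(
        genome_length=400_000,
        n_true_sites=8,
        n_decoy_sites=40,
        n_genes=400,
        n_bound_genes=60,
        seed=7,
    )
    return simulate_study(params)
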