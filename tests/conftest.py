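import numpy as np
import pytest

from phiskit._motifs import GROUP_NAMES
from phiskit.pipeline import PipelineConfig, run_pipeline
from phiskit.synthetic_data import (
    FamilySpec,
    SimulationConfig,
    reference_transposases,
    simulate,
)


@pytest.fixture(scope="session")
def queries():
    return reference_transposases()


@pytest.fixture(scope="session")
def small_sim():
    """Six-group genome small enough for fast unit tests."""
    cfg = SimulationConfig(
        genome_length=400_000,
        seed=11,
        families=[FamilySpec(group=g, n_copies=8) for g in GROUP_NAMES],
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """Six groups, no divergence, no truncation: exact-arithmetic oracle."""
    cfg = SimulationConfig(
        genome_length=400_000,
        seed=5,
        families=[
            FamilySpec(group=g, n_copies=5, divergence=0.0, truncated_fraction=0.0)
            for g in GROUP_NAMES
        ],
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_run(small_sim, queries):
    return run_pipeline(small_sim.genome, queries, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
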