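import numpy as np
import pytest

from mcpain import toy_parcellation
from mcpain.simulate import CohortSpec, generate_cohort, planted_matching


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort shared across tests (fixed seed)."""
    spec = CohortSpec(
        n_participants=24,
        n_rois=8,
        n_voxels=400,
        planted_edges=planted_matching(8, 4),
        target_r2=0.7,
        seed=7,
    )
    samples, phenotypes, truth = generate_cohort(spec)
    return spec, samples, phenotypes, truth


@pytest.fixture(scope="session")
def parc8():
    return toy_parcellation(8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
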