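import numpy as np
import pytest

from morphnet.network import build_network
from morphnet.simulate import SimulationConfig, make_default_atlas, simulate_cohort


@pytest.fixture(scope="session")
def small_atlas():
    """Bilateral 3 gyral + 3 sulcal + 1 ambiguous per hemisphere."""
    return make_default_atlas(3, 3, 1)


@pytest.fixture(scope="session")
def tiny_cohort(small_atlas):
    """8 subjects, 2 sessions, default parameters."""
    cfg = SimulationConfig(n_subjects=8, n_sessions=2, seed=42)
    return simulate_cohort(cfg, small_atlas)


@pytest.fixture(scope="session")
def tiny_networks(small_atlas, tiny_cohort):
    """Per-session lists of each subject's similarity network."""
    return [
        [
            build_network(tiny_cohort.feature_map(s, t), small_atlas)
            for s in range(8)
        ]
        for t in range(2)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
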