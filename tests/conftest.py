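import numpy as np
import pytest

from graspref.design_space import enumerate_pairs, make_configurations
from graspref.synthetic import SimulationSpec, simulate_patterns


@pytest.fixture(scope="session")
def configs():
    return make_configurations()


@pytest.fixture(scope="session")
def pairs(configs):
    return enumerate_pairs(configs)


@pytest.fixture(scope="session")
def pair_by_name(pairs):
    return {p.name: p for p in pairs}


@pytest.fixture
def small_null_dataset():
    """Fast 4-run null dataset for structural decoding tests."""
    vis, _ = simulate_patterns(
        SimulationSpec(coding_scheme="null", n_voxels=10, n_runs_per_modality=4, seed=11)
    )
    return vis


@pytest.fixture
def gc_dataset():
    """High-SNR gaze-centered dataset (8 runs, 40 voxels)."""
    vis, _ = simulate_patterns(
        SimulationSpec(coding_scheme="gaze_centered", n_voxels=40,
                       n_runs_per_modality=8, snr=8.0, seed=3)
    )
    return vis


def seeds(n, base=0):
    return [base + i for i in range(n)]
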