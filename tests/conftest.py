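import pytest

from wwprofiler.screen import load_reference_matrix, load_suspects
from wwprofiler.simulate import build_ground_truth, study_preset


@pytest.fixture(scope="session")
def suspects():
    return load_suspects()


@pytest.fixture(scope="session")
def suspects_by_name(suspects):
    return {e.name: e for e in suspects}


@pytest.fixture(scope="session")
def reference_matrix():
    return load_reference_matrix()


@pytest.fixture(scope="session")
def clean_config():
    """Small jitter-free campaign configuration used across tests."""
    return study_preset(seed=11, n_background=150, mass_jitter_ppm=0.0,
                        rt_jitter_min=0.0)


@pytest.fixture(scope="session")
def clean_ground_truth(clean_config):
    return build_ground_truth(clean_config)
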