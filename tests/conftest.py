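import numpy as np
import pytest

from nirslat import SimulationConfig, SubjectMeta, default_montage, simulate_subject


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def noise_free_subject(montage):
    """One artifact-free control subject (forward-model oracle)."""
    cfg = SimulationConfig(seed=5).noise_free()
    meta = SubjectMeta("oracle-01", "control", "none")
    return simulate_subject(cfg, montage, meta, seed=11)


@pytest.fixture(scope="session")
def noisy_subject(montage):
    """One control subject under the default (noisy) study conditions."""
    cfg = SimulationConfig(seed=9)
    meta = SubjectMeta("noisy-01", "control", "none")
    return simulate_subject(cfg, montage, meta, seed=3)


def pytest_configure(config):
    # keep hypothesis runs reproducible
    try:
        from hypothesis import settings

        settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
        settings.load_profile("ci")
    except ImportError:
        pass
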