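import numpy as np
import pytest

from ppntract.phantom import PhantomConfig, generate_subject


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def subject0(phantom_config):
    """One jittered phantom subject with full ground truth (shared)."""
    return generate_subject(phantom_config, 0, 0)


@pytest.fixture(scope="session")
def template_subject():
    """A subject with zero jitter: subject space == template space."""
    cfg = PhantomConfig(max_translation_mm=0.0, max_rotation_deg=0.0)
    return generate_subject(cfg, 0, 123)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
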