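import numpy as np
import pytest

from handsyn import SynthConfig, generate_cohort, make_toy_fixture


@pytest.fixture(scope="session")
def toy_cohort():
    """Deterministic miniature cohort: 2 subjects x 2 tasks x 200 frames."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions: 8 subjects, 6 tasks, 2 planted
    coordinations, 5 deg loading jitter, 1 deg measurement noise."""
    return generate_cohort(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise, zero-jitter cohort for exact-recovery checks."""
    cfg = SynthConfig(
        n_subjects=4,
        n_tasks=3,
        frames_per_task=400,
        noise_sd_deg=0.0,
        subject_loading_jitter_deg=0.0,
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
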