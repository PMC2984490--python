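import numpy as np
import pytest

from pulseicp.evaluate import annotate_corpus
from pulseicp.simulate import MorphologyProfile, make_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def separated_profile():
    """Noiseless, drift-free, always-present, well-separated components."""
    return MorphologyProfile(
        latency_means=(110.0, 210.0, 320.0),
        latency_sds=(0.0, 0.0, 0.0),
        amplitude_means=(3.0, 2.4, 1.7),
        amplitude_sds=(0.0, 0.0, 0.0),
        missing_probs=(0.0, 0.0, 0.0),
        noise_sd=0.0,
        drift_amplitude=0.0,
        challenge_level=0.0,
    )


@pytest.fixture
def jittered_profile():
    """Well-separated components with moderate latency jitter, no nuisance."""
    return MorphologyProfile(
        latency_means=(110.0, 210.0, 320.0),
        latency_sds=(6.0, 7.0, 8.0),
        amplitude_means=(3.0, 2.4, 1.7),
        amplitude_sds=(0.3, 0.3, 0.25),
        missing_probs=(0.0, 0.0, 0.0),
        noise_sd=0.0,
        drift_amplitude=0.0,
        challenge_level=0.0,
    )


@pytest.fixture(scope="session")
def small_corpus():
    return make_corpus(n_patients=6, files_per_patient=2, pulses_per_file=12,
                       challenge_mix=0.5, rng_seed=11)


@pytest.fixture(scope="session")
def small_annotated(small_corpus):
    return annotate_corpus(small_corpus)
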