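import numpy as np
import pytest

from pcgdx import SynthConfig, extract_cohort_features, synthesize_cohort, synthesize_pcg


@pytest.fixture(scope="session")
def cohort86_features():
    """Feature matrix of the default 24-normal / 62-murmur synthetic cohort.

    Built once per session through the full pipeline (resample is a no-op at
    2 kHz; normalize, denoise, segment, featurize); shared by the classifier
    and acceptance tests.
    """
    cohort = synthesize_cohort(24, 62, seed=7, duration=20.0)
    x, y, ids, failures = extract_cohort_features(
        [m.signal for m in cohort.members], cohort.labels
    )
    assert not failures, f"cohort recordings failed segmentation: {failures}"
    return x, y


@pytest.fixture(scope="session")
def normal_recording():
    """One murmur-free recording at 90 bpm with its ground truth."""
    return synthesize_pcg(SynthConfig(heart_rate=90.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
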