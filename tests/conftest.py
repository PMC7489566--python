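import numpy as np
import pytest

from collesmetrics import PhantomParams, generate_phantom, preprocess


@pytest.fixture(scope="session")
def default_phantom():
    """A rotated phantom with collimator frame — the standard test subject."""
    return generate_phantom(PhantomParams(seed=3))


@pytest.fixture(scope="session")
def preprocessed_phantom(default_phantom):
    """(PreprocessResult, truth, landmarks on the rotated canvas)."""
    radiograph, truth = default_phantom
    result = preprocess(radiograph)
    pts = result.transform_landmarks(truth.landmarks.as_array())
    return result, truth, pts


@pytest.fixture(scope="session")
def flat_phantom():
    """Unrotated phantom: render coordinates equal image coordinates."""
    return generate_phantom(PhantomParams(rotation_deg=0.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
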