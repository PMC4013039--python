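import numpy as np
import pytest

import gliosegkit as gk


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: intensities equal the class means exactly."""
    spec = gk.PhantomSpec(noise_sd=0.0, seed=7)
    study, labels = gk.generate_phantom(spec)
    return spec, study, labels


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom at the default (moderate) noise level."""
    spec = gk.PhantomSpec(seed=11)
    study, labels = gk.generate_phantom(spec)
    return spec, study, labels


@pytest.fixture(scope="session")
def preprocessed_phantom(noisy_phantom):
    _, study, labels = noisy_phantom
    prep = gk.preprocess_study(study, register=False)
    return prep, labels


def random_label_map(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    codes = rng.integers(0, 5, size=shape).astype(np.uint8)
    return gk.LabelMap(codes=codes, spacing=spacing)
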