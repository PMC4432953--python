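import numpy as np
import pytest

from ishannot import easy_config, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_easy_dataset():
    """30 easy-setting genes over 4 disjoint structures; shared across tests."""
    stacks, ontology, table = generate_dataset(
        30, undetected_fraction=0.7, config=easy_config(), seed=11
    )
    return stacks, ontology, table


@pytest.fixture(scope="session")
def textured_image():
    """Reproducible image with gradient energy everywhere."""
    g = np.random.default_rng(7)
    base = g.random((256, 256))
    x = np.linspace(0, 8 * np.pi, 256)
    return np.clip(0.5 + 0.3 * np.sin(x)[None, :] * np.cos(x)[:, None] + 0.1 * base, 0, 1)
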