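import numpy as np
import pytest

from cspress import phantom, sampling


@pytest.fixture(scope="session")
def dataset():
    """Default randomized phantom family: 20 references + 1 test, 128x128."""
    return phantom.make_dataset(128, 20, seed=0)


@pytest.fixture(scope="session")
def ref_kspaces(dataset):
    return [phantom.to_kspace(r) for r in dataset.references]


@pytest.fixture(scope="session")
def test_kspace(dataset):
    return phantom.to_kspace(dataset.test)


@pytest.fixture(scope="session")
def epress_quarter_mask(ref_kspaces):
    """ePRESS point mask at 4x acceleration on the default dataset."""
    wpdf = sampling.apply_window(sampling.build_ipdf(ref_kspaces, "point"), 0.8)
    return sampling.select_mask(wpdf, round(0.25 * 128 * 128), "point", 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
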