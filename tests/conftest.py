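import logging

import numpy as np
import pytest

logging.getLogger("chickseg").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small deterministic synthetic COCO dataset shared across tests."""
    from chickseg import synthetic as S

    ds, pixels, scenes = S.make_dataset(10, seed=101)
    return ds, pixels, scenes
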