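import numpy as np
import pytest

from advagree.attacks import make_shape_dataset, train_classifier


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def shape_data():
    return make_shape_dataset(
        n_classes=10, n_per_class=60, image_size=32, noise_sd=0.15,
        rng=np.random.default_rng(7),
    )


@pytest.fixture(scope="session")
def shape_classifier(shape_data):
    return train_classifier(shape_data, rng=np.random.default_rng(8))
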