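import numpy as np
import pytest

from stromaquant.classifier import ClassifierConfig, train_classifier
from stromaquant.synthetic import TexturePalette, gen_patch_dataset


@pytest.fixture(scope="session")
def easy_palette() -> TexturePalette:
    return TexturePalette(difficulty=0.0)


@pytest.fixture(scope="session")
def easy_patch_data(easy_palette):
    """Small difficulty-0 benchmark: 40 train / 15 test patches per class."""
    x_train, y_train = gen_patch_dataset(easy_palette, 40, 64, seed=11)
    x_test, y_test = gen_patch_dataset(easy_palette, 15, 64, seed=12)
    return x_train, y_train, x_test, y_test


@pytest.fixture(scope="session")
def trained_model(easy_patch_data):
    """Compact CNN trained on the difficulty-0 fixture (reused across tests)."""
    x_train, y_train, _, _ = easy_patch_data
    config = ClassifierConfig(epochs=8, batch_size=64, learning_rate=0.1, lr_decay_per_batch=0.95, seed=7)
    return train_classifier(x_train, y_train, config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
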