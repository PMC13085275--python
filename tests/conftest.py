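import numpy as np
import pytest

from paplite.fixtures import (FixtureSpec, generate_image_array,
                              high_separability_morphologies)
from paplite.nn import TrainingConfig, build_attention_model, train_model


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_image_set():
    """3-class, 15 images/class, 32x32, strongly separated morphologies."""
    spec = FixtureSpec(
        n_classes=3, per_class_counts=[15, 15, 15], image_size=(32, 32),
        class_morphology=high_separability_morphologies(3), seed=11,
    )
    images, labels = generate_image_array(spec)
    return images, labels


@pytest.fixture(scope="session")
def trained_toy_model(small_image_set):
    """A briefly trained toy attention CNN shared across extraction and
    explanation tests (training is deterministic, so sharing is safe)."""
    images, labels = small_image_set
    model = build_attention_model("toy_cnn", 3, seed=5)
    train_model(model, images, labels,
                TrainingConfig(epochs=3, learning_rate=0.01, seed=5))
    return model
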