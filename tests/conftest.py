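import numpy as np
import pytest

from hemocount import (CellCounter, RoiClassifier, SceneParams,
                       make_chamber_image, make_phone_image, make_training_set)

# Reduced classifier input size used throughout the tests: the architecture
# (conv 256 -> pool -> conv 128 -> pool -> dense 128-128-64-2) is unchanged,
# only the spatial resolution is scaled down to keep single-CPU runtimes short.
TEST_INPUT_SIZE = (32, 32)


@pytest.fixture(scope="session")
def chamber_scene():
    """Default chamber scene, seed 0: image plus exact truth."""
    return make_chamber_image(SceneParams(seed=0))


@pytest.fixture(scope="session")
def phone_scene():
    """Default phone scene, seed 0."""
    return make_phone_image(SceneParams(seed=0))


@pytest.fixture(scope="session")
def counter():
    return CellCounter()


@pytest.fixture(scope="session")
def trained_clf():
    """A ROI classifier trained once per session on a small synthetic set."""
    images, labels = make_training_set(150, 150, seed=1)
    clf = RoiClassifier(input_size=TEST_INPUT_SIZE, epochs=8, random_state=0)
    clf.fit(images, labels)
    assert clf.history_["val_accuracy"][-1] >= 0.9, "session classifier failed to train"
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
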