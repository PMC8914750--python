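import numpy as np
import pytest

import fmgrip as fg
from fmgrip import preprocess


@pytest.fixture()
def default_cfg():
    return fg.SynthConfig(seed=0)


@pytest.fixture()
def zero_noise_cfg():
    return fg.SynthConfig(
        seed=0, noise=fg.NoiseConfig(photo_sd=0.0, hall_sd=0.0, force_sd=0.0))


@pytest.fixture(scope="session")
def small_windows():
    """120 labeled Hall windows (40 per angle) at default noise."""
    cfg = fg.SynthConfig(seed=0)
    return fg.make_angle_dataset(cfg, windows_per_angle=40, rng_seed=7)


@pytest.fixture(scope="session")
def trained_clf(small_windows):
    """Angle CNN fitted on a stratified 4:1 split of the small dataset."""
    train, test = preprocess.split_dataset(small_windows, rng_seed=3)
    X, y = preprocess.windows_to_matrix(train)
    clf = fg.AngleCNNClassifier(random_state=0).fit(X, y)
    return clf, train, test


@pytest.fixture(scope="session")
def full_result():
    """The desk-scale reference experiment (3 x 333 windows, seed 42)."""
    return fg.run_experiment(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
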