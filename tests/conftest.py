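import numpy as np
import pytest

from trustex import PhantomConfig, generate_arrays
from trustex.pipeline import FusionConfig, fuse_features
from trustex.preprocess import preprocess_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom_cfg():
    """Tiny two-class phantom: 4 cases/class x 3 images, fast patches."""
    return PhantomConfig.two_class(
        0.2, n_cases_per_class=4, images_per_case=3, height=32, width=48, seed=99
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Identical-class phantom dataset with fused features (200 images, 40 cases)."""
    cfg = PhantomConfig(
        theta_neg=(0.05, 0.05, 0.0, 0.0), theta_pos=(0.05, 0.05, 0.0, 0.0), seed=7
    )
    return _featurize(cfg)


@pytest.fixture(scope="session")
def signal_dataset():
    """Separable phantom dataset (theta gap 0.2) with fused features."""
    return _featurize(PhantomConfig.two_class(0.2, seed=11))


def _featurize(cfg):
    images, y, cases = generate_arrays(cfg)
    feats = [fuse_features(preprocess_image(im), FusionConfig()) for im in images]
    X = np.array([f.values for f in feats])
    return X, y, cases, feats[0].schema
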