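import numpy as np
import pytest

from habitatkit import PhantomParams, generate_phantom, preprocess_study


@pytest.fixture(scope="session")
def small_params():
    """Compact phantom (~900 ROI voxels) used throughout the unit tests."""
    return PhantomParams(grid_shape=(16, 16, 16), tumor_radius=6.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_study():
    """Zero-noise 3-habitat phantom plus its ground truth."""
    params = PhantomParams(
        grid_shape=(16, 16, 16), tumor_radius=6.0, noise_sd=0.0, seed=7
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def noiseless_features(noiseless_study):
    """Standardized (unsmoothed) feature matrix of the zero-noise phantom."""
    study, truth = noiseless_study
    _, fm = preprocess_study(study, smooth=False)
    return fm, truth


def random_clustered_instance(rng, n_max=200, d_choices=(2, 6), k_choices=(2, 3, 4)):
    """A random labelled point set with every cluster nonempty."""
    k = int(rng.choice(k_choices))
    n = int(rng.integers(max(k + 2, 10), n_max + 1))
    d = int(rng.choice(d_choices))
    centers = rng.normal(0, 5, size=(k, d))
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(labels)
    X = centers[labels] + rng.normal(0, 1.0, size=(n, d))
    return X, labels + 1, k
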