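import numpy as np
import pytest

import polarforest as pf


def random_optical_params(rng: np.random.Generator) -> pf.OpticalParams:
    """A random physically valid parameter set (used across test modules)."""
    d = rng.uniform(0, 0.6)
    cd = rng.uniform(-0.5, 0.5)
    norm = np.hypot(d, cd)
    if norm > 0.95:
        d, cd = d * 0.95 / norm, cd * 0.95 / norm
    return pf.OpticalParams(
        d=d,
        theta_d=rng.uniform(-np.pi, np.pi),
        cd=cd,
        delta=rng.uniform(0, np.pi),
        theta_r=rng.uniform(-np.pi, np.pi),
        psi=rng.uniform(-np.pi / 4, np.pi / 4),
        a=rng.uniform(0.2, 1.0),
        b=rng.uniform(0.2, 1.0),
        c=rng.uniform(0.2, 1.0),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210705)


@pytest.fixture(scope="session")
def small_dataset():
    """~200-row well-separated synthetic dataset shared by forest/training tests."""
    cfg = pf.balanced_config(
        seed=11, train_samples=2, test_samples=2, points_per_sample=25, test_points_per_sample=15
    )
    return pf.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The shipped default (reference-count) dataset at a fixed seed."""
    return pf.generate_dataset(pf.default_config(seed=5))
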