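"""Shared fixtures: small phantoms and random label volumes."""

import numpy as np
import pytest

import gliounet as g


@pytest.fixture(scope="session")
def phantom48():
    """A small deterministic phantom with all four tissue classes."""
    cfg = g.PhantomConfig(shape=(48, 48, 48), rng_seed=7)
    return g.generate_phantom(cfg)


@pytest.fixture(scope="session")
def phantom48_noiseless():
    cfg = g.PhantomConfig(shape=(48, 48, 48), noise_sd=0.0, rng_seed=7)
    return g.generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240612)


def random_label_volume(rng, shape=(16, 16, 16), p_tumor=0.2):
    """Sparse random BraTS-convention labels (mostly background)."""
    labels = np.zeros(shape, np.int16)
    n = int(p_tumor * np.prod(shape))
    idx = rng.choice(np.prod(shape), size=n, replace=False)
    vals = rng.choice([1, 2, 4], size=n)
    labels.flat[idx] = vals
    return g.LabelVolume(labels, "brats")
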