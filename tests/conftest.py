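import numpy as np
import pytest

from mayseg.kapur import Histogram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_hist():
    return Histogram.from_probs(np.full(256, 1 / 256))


@pytest.fixture
def random_hist(rng):
    probs = rng.random(256)
    return Histogram.from_probs(probs / probs.sum())


def make_mixture_hist(rng, n_modes=3, levels=256, floor=1e-6):
    """Histogram of a mixture of Gaussian intensity modes over a small
    uniform noise floor (image histograms are never exactly zero)."""
    centers = np.sort(rng.choice(np.arange(30, levels - 30), size=n_modes, replace=False))
    x = np.arange(levels)
    probs = np.full(levels, floor)
    for c in centers:
        probs += np.exp(-0.5 * ((x - c) / rng.uniform(5, 12)) ** 2)
    probs /= probs.sum()
    return Histogram.from_probs(probs)
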