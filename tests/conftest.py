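import numpy as np
import pytest
from scipy import stats

from covertbci.epochs import ChannelMontage, EpochSet, standard_montage


@pytest.fixture(scope="session")
def montage29():
    return standard_montage()


@pytest.fixture
def small_montage():
    names = ("A1", "A2", "A3", "A4")
    pos = np.array([[0.0, 0.3], [0.3, 0.0], [0.0, -0.3], [-0.3, 0.0]])
    return ChannelMontage(names, pos, {"front": ("A1",)})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_epochs(rng, n_trials=8, n_channels=4, n_samples=100, fs=500.0,
                t0_ms=-100.0, montage=None):
    if montage is None:
        names = tuple(f"c{i}" for i in range(n_channels))
        pos = np.stack([
            0.5 * np.cos(2 * np.pi * np.arange(n_channels) / n_channels),
            0.5 * np.sin(2 * np.pi * np.arange(n_channels) / n_channels),
        ], axis=1)
        montage = ChannelMontage(names, pos)
    data = rng.standard_normal((n_trials, len(montage), n_samples))
    labels = np.array(["yes", "no"] * (n_trials // 2) + ["yes"] * (n_trials % 2))
    return EpochSet(data, labels, fs, t0_ms, montage)


@pytest.fixture
def noise_epochs(rng):
    return make_epochs(rng)


def binomial_band(n, p=0.5, conf=0.99):
    """Exact two-sided binomial interval for a success fraction."""
    lo = stats.binom.ppf((1 - conf) / 2, n, p) / n
    hi = stats.binom.ppf(1 - (1 - conf) / 2, n, p) / n
    return lo, hi
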