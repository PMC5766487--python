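import numpy as np
import pytest

from spikekin.core import DecoderDataset, KinematicsSeries, Normalization, SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def poisson_train(rate: float, duration: float, seed: int, unit_id: int = 1) -> SpikeTrain:
    """Homogeneous Poisson spike train (test helper)."""
    r = np.random.default_rng(seed)
    n = r.poisson(rate * duration)
    times = np.sort(r.uniform(0.0, duration, size=n))
    # nudge exact duplicates (vanishing probability, but keep strictness)
    while times.size > 1 and np.any(np.diff(times) <= 0):
        dup = np.concatenate(([False], np.diff(times) <= 0))
        times = np.sort(times + dup * 1e-12)
    return SpikeTrain(times, unit_id, duration)


def simple_dataset(X: np.ndarray, Y: np.ndarray, fs: float = 20.0) -> DecoderDataset:
    """Wrap plain matrices into a DecoderDataset with identity normalization."""
    cols = [f"x{i}" for i in range(X.shape[1])]
    norm = Normalization(np.zeros(X.shape[1]), np.ones(X.shape[1]), cols)
    return DecoderDataset(
        inputs=X,
        targets=Y,
        times=np.arange(X.shape[0]) / fs,
        fs=fs,
        lag_count=0,
        normalization=norm,
    )


@pytest.fixture
def small_kin():
    t = np.arange(0, 600) / 100.0
    return KinematicsSeries(
        times=t,
        hip=115.0 + 20.0 * np.sin(2 * np.pi * t / 2.0),
        knee=100.0 + 25.0 * np.sin(2 * np.pi * t / 2.0 + 0.7),
        ankle=90.0 + 25.0 * np.sin(2 * np.pi * t / 2.0 + 1.4),
        rate=100.0,
    )
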