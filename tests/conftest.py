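import numpy as np
import pytest

from ppgsleep import CohortSpec, SleepStager, simulate_cohort
from ppgsleep.nn.stager import BlockSpec, StagerSpec


@pytest.fixture(scope="session")
def tiny_spec():
    """A miniature stager spec (64-sample windows) for fast training tests."""
    return StagerSpec(
        input_len=64, stem_kernel=5, stem_stride=2, stem_channels=4,
        blocks=(BlockSpec(3, 1, 4, 1, 1), BlockSpec(3, 2, 6, 2, 1)),
        head_channels=8, lstm_units=6, dense_units=6)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight 1-h nights with PPG at 64 Hz, two per severity category."""
    spec = CohortSpec(n_per_category=(2, 2, 2, 2), duration_s=3600,
                      ppg_fs=64.0, seed=11)
    return simulate_cohort(spec)


@pytest.fixture()
def untrained_model():
    from ppgsleep.nn.stager import compact_spec

    return SleepStager(compact_spec(), n_classes=5, seed=0)


def toy_windows(tiny_spec, n, n_classes, seed=0, separation=3.0):
    """Linearly separable window/label pairs for the tiny stager.

    Class ``l`` is a constant offset ``(l - (k-1)/2) * separation`` plus
    noise, trivially separable through global average pooling.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=n)
    offsets = (labels - (n_classes - 1) / 2) * separation
    windows = offsets[:, None] + 0.3 * rng.normal(
        size=(n, tiny_spec.input_len))
    return windows, labels
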