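"""Shared fixtures: analytic tones and seeded synthetic subjects.

The heavier synthetic feature tables are session-scoped so the EMD work is
done once and reused across the channel-selection and evaluation tests.
"""

import numpy as np
import pytest

from emdeeg import SyntheticSpec, make_two_class_dataset
from emdeeg.features import feature_table

FS = 128.0


@pytest.fixture(scope="session")
def time_axis():
    return np.arange(640) / FS  # 5 s at 128 Hz


@pytest.fixture(scope="session")
def tone_8hz(time_axis):
    return np.sin(2 * np.pi * 8 * time_axis)


@pytest.fixture(scope="session")
def two_tone(time_axis):
    """Well-separated 32 Hz + 4 Hz pair, the canonical EMD separation case."""
    return (
        np.sin(2 * np.pi * 32 * time_axis) + np.sin(2 * np.pi * 4 * time_axis),
        np.sin(2 * np.pi * 32 * time_axis),
        np.sin(2 * np.pi * 4 * time_axis),
    )


@pytest.fixture(scope="session")
def ranking_table():
    """IMF1 feature table of an 8-channel subject with planted channels 2 and 7.

    40 trials of 10 s (2 segments each), separation 3.0, seed 11 — strong,
    unambiguous class structure confined to channels ch02 and ch07.
    """
    spec = SyntheticSpec(
        n_subjects=1, n_trials=40, trial_sec=10.0, n_channels=8,
        informative_channels=(2, 7), separation=3.0, seed=11,
    )
    ds = make_two_class_dataset(spec)[0]
    return feature_table(ds, imf_levels=(1,))
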