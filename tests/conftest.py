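import numpy as np
import pytest

import semgcodec as sc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def iso_record():
    """10 s of isometric surrogate EMG at the default operating level."""
    return sc.generate(sc.SyntheticConfig(duration_s=10.0, seed=42))


@pytest.fixture(scope="session")
def dyn_record():
    """10 s of dynamic (burst) surrogate EMG."""
    return sc.generate(
        sc.SyntheticConfig(protocol="dynamic", duration_s=10.0, seed=7)
    )


@pytest.fixture(scope="session")
def emg_windows(iso_record):
    """Length-2048 sample windows cut from the isometric surrogate."""
    return sc.segment(iso_record, 2048).windows
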