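import numpy as np
import pytest

import popgrasp as pg


@pytest.fixture(scope="session")
def null_dataset():
    """Small population with no condition dependence (homogeneous 20 Hz)."""
    cfg = pg.SynthConfig.null(
        n_units=4, n_datasets=1, trials_per_condition=10, baseline_hz=20.0, seed=42
    )
    return cfg, pg.simulate_dataset(cfg, 0)


@pytest.fixture(scope="session")
def grip_dataset():
    """Population with a single strong planted grip component."""
    cfg = pg.SynthConfig(
        n_units=6,
        n_datasets=1,
        trials_per_condition=10,
        baseline_hz=15.0,
        amplitudes={"grip": 6.0},
        seed=7,
    )
    return cfg, pg.simulate_dataset(cfg, 0)


@pytest.fixture(scope="session")
def grip_rates(grip_dataset):
    _, ds = grip_dataset
    return pg.build_rate_tensor(ds)


@pytest.fixture(scope="session")
def null_rates(null_dataset):
    _, ds = null_dataset
    return pg.build_rate_tensor(ds)
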