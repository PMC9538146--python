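"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

import lagfuse as lf
from lagfuse.pipeline import filter_epochs


@pytest.fixture(scope="session")
def coupled_recording():
    """One coupled EEG/sEMG recording with the default 35-sample lag."""
    return lf.simulate_coupled_pair(lf.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_epochs():
    """Filtered 8-class epoch set, 2 trials per class (desk scale)."""
    ep = lf.simulate_movement_dataset(lf.SimConfig(seed=11, snr_db=10.0), 2)
    return filter_epochs(ep)


@pytest.fixture(scope="session")
def noise_epochs():
    """Unstructured noise epochs with modality tags, for geometry tests."""
    rng = np.random.default_rng(5)
    n_ep, C, T = 6, 5, 1200
    modality = [lf.preprocess.EEG] * 3 + [lf.preprocess.SEMG] * 2
    return lf.EpochSet(rng.standard_normal((n_ep, C, T)),
                       rng.integers(0, 2, n_ep), T // 2, 1024.0,
                       [f"c{i}" for i in range(C)], modality)
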