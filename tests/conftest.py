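import numpy as np
import pytest

import amdecode as am


@pytest.fixture(scope="session")
def tiny_spec():
    """Small cohort whose planted effect is easy to recover quickly."""
    return am.CohortSpec(
        n_subjects=2,
        group_sizes=(1, 1),
        n_trials=12,
        n_runs=2,
        grid_shape=(8, 8, 8),
        mask_fraction=0.6,
        n_informative_voxels=40,
        informative_latency=8.0,
        effect_size=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_subject(tiny_spec):
    return am.generate_subject(tiny_spec, 0)


@pytest.fixture(scope="session")
def tiny_tensor(tiny_subject):
    ds = tiny_subject
    return am.build_tensor(
        ds.timeseries, ds.mask, ds.trials, ds.tr, ds.run_length_trs
    )


@pytest.fixture
def rng():
    """Fresh deterministic generator per test, so tests stay order-independent."""
    return np.random.default_rng(20240915)
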