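import numpy as np
import pytest

from mdasl import AcquisitionParams, PhantomSpec, ROISphere, build_wd_lookup


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def lookup(params):
    return build_wd_lookup(params)


@pytest.fixture
def small_spec():
    """Reduced phantom for fast pipeline tests."""
    return PhantomSpec(
        shape=(16, 16, 12),
        rois=(ROISphere("stg_att", (5, 8, 6), 10.0, att_effect=300.0),),
        n_patients=6,
        n_controls=6,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
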