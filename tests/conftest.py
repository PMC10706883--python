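import numpy as np
import pytest

from renal_mpmri.phantom import PhantomSpec, make_phantom

ZERO_SD = {k: 0.0 for k in ("t1", "m0", "adc", "t2star", "perfusion", "att", "tau")}


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Phantom with zero intra-tissue dispersion and no acquisition noise."""
    spec = PhantomSpec(intra_tissue_sd=dict(ZERO_SD))
    masks, maps = make_phantom(spec)
    return spec, masks, maps


@pytest.fixture(scope="session")
def dispersed_phantom():
    """Default phantom: cortex T1 ~ N(1500, 50²), medulla ~ N(1900, 50²)."""
    spec = PhantomSpec(seed=7)
    masks, maps = make_phantom(spec)
    return spec, masks, maps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
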