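import numpy as np
import pytest

from formsim.absorption_pbpk import ReleaseInput, default_config
from formsim.synthetic_data import optimized_weibull, reference_weibull


@pytest.fixture(scope="session")
def ref_weibull():
    """Release curve fit to the printed reference (23/58/77%) profile."""
    return reference_weibull()


@pytest.fixture(scope="session")
def opt_weibull():
    """Release curve fit to the printed optimized (22/55/76%) profile."""
    return optimized_weibull()


@pytest.fixture()
def ir_config():
    return default_config()


@pytest.fixture()
def xr_config(ref_weibull):
    return default_config(ReleaseInput(mode="xr_weibull", weibull=ref_weibull))


@pytest.fixture()
def fast_xr_config(ref_weibull):
    """Coarser grid / shorter horizon for relative-comparison property tests."""
    cfg = default_config(ReleaseInput(mode="xr_weibull", weibull=ref_weibull))
    cfg.duration = 48.0
    cfg.grid = 0.1
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
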