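import numpy as np
import pytest

from tvddm import DDMParams, TVDDMParams, SimConfig

# Reference parameter values used across the suite: the prior means of the
# informed truncated-normal priors for each model.
DDM_REF = DDMParams(A=0.17, ter=0.26, v=0.25, sz=0.05, sv=0.07, ster=0.28)
DDM_REF_PURE = DDMParams(A=0.17, ter=0.26, v=0.25)  # no between-trial variability
TVDDM_REF = TVDDMParams(A=0.2, ter=0.18, v=0.3, beta=25.0, n=5.0, sigma2=0.1, sv=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_cfg():
    return SimConfig()
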