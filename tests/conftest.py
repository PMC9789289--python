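import numpy as np
import pytest

from easfiber.population import CENTRAL, PERIPHERAL, FiberParams


@pytest.fixture(scope="session")
def mean_fiber() -> FiberParams:
    """Fiber with every randomized parameter at its distribution mean."""
    c_per = 10.0**PERIPHERAL.cap_mu * 1e9 - PERIPHERAL.cap_alpha
    c_cen = 10.0**CENTRAL.cap_mu * 1e9 - CENTRAL.cap_alpha
    return FiberParams(
        cf=1.0, sr=0.0, sr_group="HSR",
        t_abs=450e-6, t_rel=512.5e-6,
        C_per=c_per, C_cen=c_cen,
        tau_supra_per=PERIPHERAL.tau_supra0,
        tau_supra_cen=CENTRAL.tau_supra0,
        t_dead=450e-6,
    )


@pytest.fixture(scope="session")
def hsr_fiber(mean_fiber) -> FiberParams:
    """Mean-parameter fiber with a high spontaneous rate."""
    import dataclasses
    return dataclasses.replace(mean_fiber, sr=70.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
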