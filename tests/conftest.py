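import numpy as np
import pytest

from dcerrm import AcquisitionProtocol, AifSpec, TissueKinetics


@pytest.fixture
def protocol() -> AcquisitionProtocol:
    """Study acquisition: TR_ref 100 ms / FA 5, TR_dce 8.09 ms / FA 30,
    dt 13.32 s, 40 frames, 3 baseline."""
    return AcquisitionProtocol()


@pytest.fixture
def muscle() -> TissueKinetics:
    """Fixed skeletal-muscle reference kinetics."""
    return TissueKinetics(0.045, 0.08)


@pytest.fixture
def aif() -> AifSpec:
    """Default double-dose biexponential bolus arriving after baseline."""
    return AifSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170330)
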