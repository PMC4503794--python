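import numpy as np
import pytest

from qmtpipe.signal_models import (
    AcquisitionSpec,
    TwoPoolParams,
    default_protocol,
    protocol_arrays,
)
from qmtpipe.synthetic_cohort import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def bssfp_arrays(protocol):
    return protocol_arrays(protocol)


@pytest.fixture(scope="session")
def gray_tissue():
    return TwoPoolParams(m0=820.0, f=0.10, kf=2.4, t1f=1.2, t2f=0.090)


@pytest.fixture(scope="session")
def reference_seq():
    return AcquisitionSpec(kind="bssfp", flip_angle=35.0, tr=4.81, trf=1.15)


@pytest.fixture(scope="session")
def phantom():
    return build_phantom(PhantomSpec(), seed=0)


@pytest.fixture(scope="session")
def tiny_phantom():
    return build_phantom(PhantomSpec(shape=(16, 16, 4)), seed=0)
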