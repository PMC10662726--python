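import numpy as np
import pytest

import eyeperf as ep


@pytest.fixture(scope="session")
def eye():
    return ep.EyeParams()


@pytest.fixture(scope="session")
def sys_cf():
    return ep.SystemParams()


@pytest.fixture(scope="session")
def sys_cpg1():
    return ep.SystemParams(system_resistance=10.0)


@pytest.fixture(scope="session")
def sys_cpg2():
    return ep.SystemParams(system_resistance=0.6)


@pytest.fixture(scope="session")
def sys_cpp():
    return ep.SystemParams(feedback_gain=7.0)


def system_for(mode, gain):
    if mode == "CF":
        return ep.SystemParams()
    if mode == "CPg":
        return ep.SystemParams(system_resistance=gain)
    return ep.SystemParams(feedback_gain=gain)


@pytest.fixture(scope="session")
def exvivo_record():
    return ep.synth_exvivo(60.0, seed=1234)
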