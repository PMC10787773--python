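import numpy as np
import pytest
from dataclasses import replace

from gravinet import (
    GRAVITY_CASE,
    GeometrySpec,
    RheologyParams,
    WaveformSpec,
    apply_microgravity,
    generate_inflow,
    generate_network,
    run_case,
)


@pytest.fixture(scope="session")
def params():
    return RheologyParams()


@pytest.fixture(scope="session")
def default_network():
    return generate_network()


@pytest.fixture(scope="session")
def coarse_dt():
    # coarse sampling keeps full-network case runs fast; the quasi-static
    # solver has no time-step accuracy constraint
    return 0.01


@pytest.fixture(scope="session")
def coarse_wave(coarse_dt):
    return generate_inflow(WaveformSpec(), dt=coarse_dt)


@pytest.fixture(scope="session")
def gravity_result(default_network, coarse_wave, coarse_dt):
    cc = replace(GRAVITY_CASE, dt=coarse_dt)
    return run_case(default_network, coarse_wave, cc)


@pytest.fixture(scope="session")
def microgravity_setup(default_network, coarse_wave, coarse_dt):
    cc_g = replace(GRAVITY_CASE, dt=coarse_dt)
    wave_u, outlets_u, cc_u = apply_microgravity(
        coarse_wave, default_network.outlets, cc_g
    )
    cc_u = replace(cc_u, dt=coarse_dt)
    net_u = default_network.replace_outlets(outlets_u)
    return net_u, wave_u, cc_u


@pytest.fixture(scope="session")
def microgravity_result(microgravity_setup):
    net_u, wave_u, cc_u = microgravity_setup
    return run_case(net_u, wave_u, cc_u)
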