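"""Shared fixtures.  Everything is seeded; fixtures that are expensive to
build are session-scoped and treated as read-only by the tests."""

import numpy as np
import pytest

from kvperm import (
    GeneratorParams,
    SiteLabelSeries,
    build_pore_model,
    emit_coordinates,
    make_scaffold,
    simulate_knockon,
)


@pytest.fixture(scope="session")
def scaffold():
    return make_scaffold()


@pytest.fixture(scope="session")
def model(scaffold):
    return build_pore_model(scaffold)


@pytest.fixture(scope="session")
def base_params():
    return GeneratorParams(seed=1)


@pytest.fixture(scope="session")
def base_log(base_params):
    """Default uninhibited run: 24.5 us at 100 mV, seed 1."""
    return simulate_knockon(base_params)


@pytest.fixture(scope="session")
def base_series(base_log, model):
    return SiteLabelSeries.from_eventlog(base_log, model)


@pytest.fixture(scope="session")
def short_params():
    return GeneratorParams(seed=2, duration_us=0.5)


@pytest.fixture(scope="session")
def short_log(short_params):
    return simulate_knockon(short_params)


@pytest.fixture(scope="session")
def short_frames(short_log, model, short_params):
    return emit_coordinates(short_log, model, short_params)


@pytest.fixture(scope="session")
def noiseless_params():
    return GeneratorParams(seed=3, duration_us=0.5, sigma_z_A=0.0, sigma_xy_A=0.0)


@pytest.fixture(scope="session")
def noiseless_frames(noiseless_params, model):
    log = simulate_knockon(noiseless_params)
    return log, emit_coordinates(log, model, noiseless_params)


@pytest.fixture(scope="session")
def ry785_run(model):
    params = GeneratorParams.for_mode("RY785", 11, duration_us=0.5)
    log = simulate_knockon(params)
    return params, log, emit_coordinates(log, model, params)


@pytest.fixture(scope="session")
def tea_run(model):
    params = GeneratorParams.for_mode("TEA", 5, duration_us=2.0)
    log = simulate_knockon(params)
    return params, log, emit_coordinates(log, model, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
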