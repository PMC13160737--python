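import pytest

from srlumen import (
    EffluxModel,
    InfluxModel,
    SimulationConfig,
    SRElementGeometry,
    build_axial_grid,
    load_default_parameters,
    solve,
)


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def geom():
    return SRElementGeometry()


@pytest.fixture(scope="session")
def disc_1d(geom):
    """Production axial grid: 10 nm spacing, 181 nodes."""
    return build_axial_grid(geom, 1e-8)


@pytest.fixture(scope="session")
def decaying_efflux(params):
    return EffluxModel(mode="decaying", J0=params.J_efflux_0, reference_free_ca=params.ca_free_initial)


@pytest.fixture(scope="session")
def constant_efflux(params):
    return EffluxModel(mode="constant", J0=params.J_efflux_0, reference_free_ca=params.ca_free_initial)


@pytest.fixture(scope="session")
def no_influx():
    return InfluxModel(enabled=False)


def _run(params, geom, disc, efflux, influx, **cfg_kwargs):
    cfg = SimulationConfig(**cfg_kwargs)
    return solve(cfg, params, geom, disc, efflux, influx)


@pytest.fixture(scope="session")
def run_20ms_nocasq(params, geom, disc_1d, decaying_efflux, no_influx):
    """Decaying efflux, no calsequestrin, no SERCA, 20 ms window."""
    return _run(params, geom, disc_1d, decaying_efflux, no_influx, duration=0.02, casq_enabled=False)


@pytest.fixture(scope="session")
def run_20ms_casq(params, geom, disc_1d, decaying_efflux, no_influx):
    """Decaying efflux, calsequestrin on, no SERCA, 20 ms window."""
    return _run(params, geom, disc_1d, decaying_efflux, no_influx, duration=0.02, casq_enabled=True)
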