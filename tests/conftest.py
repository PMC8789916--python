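import pytest

from hotbio import simulate, sulfate


@pytest.fixture(scope="session")
def column() -> sulfate.SedimentColumn:
    """The study column: D=0.054 m2/yr, phi=0.35, F=14, boundary 600 mbsf."""
    return sulfate.SedimentColumn()


@pytest.fixture(scope="session")
def sim_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(seed=1234, n_vials=12)


@pytest.fixture(scope="session")
def sim_tables(sim_config):
    vials, controls = simulate.simulate_incubation(sim_config)
    profile, species = simulate.simulate_profile(sim_config)
    return {"vials": vials, "controls": controls, "profile": profile, "species": species}
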