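import pytest

from tedynamics import SimulationConfig, generate_exemplar_db


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_dna=60,
        n_r1=40,
        n_r2=30,
        library_size=300_000,
        sirna_library_size={22: 100_000, 24: 200_000},
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    db, truth = generate_exemplar_db(small_config)
    return db, truth
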