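import pytest

from dmscc.chip_model import make_profile
from dmscc.synthetic_data import SimConfig, default_strain_params, simulate_experiment


@pytest.fixture(scope="session")
def cenpk_params():
    return default_strain_params("CEN.PK113-7D")


@pytest.fixture(scope="session")
def er_params():
    return default_strain_params("Ethanol Red")


@pytest.fixture(scope="session")
def excess_profile():
    return make_profile(30.0, 0.0)


@pytest.fixture(scope="session")
def limitation_profile():
    return make_profile(0.0, 30.0)


@pytest.fixture(scope="session")
def excess_table(cenpk_params, excess_profile):
    """Constant-excess control, 10 chambers (shared read-only fixture)."""
    cfg = SimConfig(profile=excess_profile, seed=42, n_chambers=10)
    return simulate_experiment(cfg, cenpk_params)


@pytest.fixture(scope="session")
def limitation_table(cenpk_params, limitation_profile):
    cfg = SimConfig(profile=limitation_profile, seed=43, n_chambers=10)
    return simulate_experiment(cfg, cenpk_params)


@pytest.fixture(scope="session")
def dynamic_table(cenpk_params):
    """9 s excess / 21 s limitation condition (f = 0.3), 10 chambers."""
    cfg = SimConfig(profile=make_profile(9.0, 21.0), seed=44, n_chambers=10)
    return simulate_experiment(cfg, cenpk_params)
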