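import numpy as np
import pytest

from il7r_pkpd.datasets import GeneratorConfig, generate_study
from il7r_pkpd.estimation import fit_dr_population
from il7r_pkpd.params import default_dr_pair, default_tmdd


@pytest.fixture(scope="session")
def tmdd_typ():
    return default_tmdd()


@pytest.fixture(scope="session")
def dr_pair():
    return default_dr_pair()


@pytest.fixture(scope="session")
def tcell_trial():
    """One virtual trial with only the T-cell streams (fast to generate)."""
    cfg = GeneratorConfig(seed=11, streams=("TEM", "TREG"))
    df, truth = generate_study(cfg)
    return cfg, df, truth


@pytest.fixture(scope="session")
def full_trial():
    """One complete five-stream virtual trial (includes TMDD simulation)."""
    cfg = GeneratorConfig(seed=7)
    df, truth = generate_study(cfg)
    return cfg, df, truth


@pytest.fixture(scope="session")
def tem_fit(tcell_trial):
    """Population TEM dose-response fit of the shared T-cell trial."""
    _, df, _ = tcell_trial
    return fit_dr_population(df, population="TEM", seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
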