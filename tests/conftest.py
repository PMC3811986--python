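import numpy as np
import pytest

import tgscan as tg
from tgscan.mmlm_lrt import RiskParams


@pytest.fixture(scope="session")
def small_duo_data():
    """A clean 100-duo, 300-marker null dataset."""
    cfg = tg.SimConfig(
        n_case_duos=50, n_control_duos=50, n_markers=300, seed=11
    )
    return tg.sim_duos(cfg)


@pytest.fixture(scope="session")
def structured_duo_data():
    """Two-stratum, Fst=0.2 dataset with status confounded with stratum."""
    cfg = tg.SimConfig(
        n_case_duos=150,
        n_control_duos=150,
        n_markers=600,
        seed=7,
        strata_weights=(0.5, 0.5),
        fst=0.2,
        status_stratum_bias=(2.5, 0.4),
    )
    return tg.sim_duos(cfg)


@pytest.fixture(scope="session")
def trio_data():
    """300 affected trios with a planted maternal effect at marker 0."""
    cfg = tg.SimConfig(
        n_trios=300, n_markers=200, seed=13,
        risk=RiskParams(s1=2.0, q=0.3), model="diff",
    )
    return tg.sim_trios(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
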