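import numpy as np
import pytest
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def small_library():
    from csmol.fixtures import FixtureSpec, gen_library

    return gen_library(FixtureSpec(n_molecules=50, seed=7))


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained encoder+head model shared across tests."""
    from csmol.encoder_model import CSSModel, desk_encoder_config, desk_head_config

    return CSSModel(
        desk_encoder_config(), head_targets=("MaxSim", "CrossSim"),
        head_cfg_factory=desk_head_config, seed=0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
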