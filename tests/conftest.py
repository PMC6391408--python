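import pytest

from tnflux.synth import WorldConfig, generate_world

TINY_MODELS = {"historical": 3, "RCP2.6": 2, "RCP4.5": 2, "RCP6.0": 2, "RCP8.5": 2}


@pytest.fixture(scope="session")
def tiny_cfg() -> WorldConfig:
    """A small, fast world configuration shared across test modules."""
    return WorldConfig(n_watersheds=12, n_huc2=3, n_models=dict(TINY_MODELS), seed=7)


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    """A fully generated small world with one bioenergy-expansion scenario."""
    world, truth = generate_world(tiny_cfg, scenarios=("SSP4-3.4",))
    return world, truth
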