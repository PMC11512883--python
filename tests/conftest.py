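import pytest

from radecon.costing import derive_cycle_costs
from radecon.parameters import (
    DEFAULT_LIFE_TABLE_PATH,
    default_config,
    load_life_table,
)


@pytest.fixture(scope="session")
def base_cfg():
    return default_config()


@pytest.fixture()
def cfg(base_cfg):
    """Mutable per-test copy of the bundled baseline configuration."""
    return base_cfg.model_copy(deep=True)


@pytest.fixture(scope="session")
def lt():
    return load_life_table(DEFAULT_LIFE_TABLE_PATH)


@pytest.fixture(scope="session")
def costs(base_cfg):
    return derive_cycle_costs(base_cfg)
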