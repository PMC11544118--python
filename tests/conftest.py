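import numpy as np
import pytest

from spongescreen.diffexpr import cpm_log_normalize
from spongescreen.simulate import (SimConfig, simulate_expression,
                                   simulate_interaction_tables)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    """The default study conditions with a fixed seed."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    """Expression + truth + log2cpm for the default conditions (shared)."""
    expr, truth = simulate_expression(default_config)
    logcpm = cpm_log_normalize(expr)
    return {"config": default_config, "expr": expr, "truth": truth,
            "logcpm": logcpm}


@pytest.fixture(scope="session")
def default_tables(default_bundle):
    return simulate_interaction_tables(default_bundle["truth"],
                                       default_bundle["config"])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
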