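import numpy as np
import pytest

from dcmsim import (
    DesignCondition,
    FitConfig,
    assign_item_models,
    build_qmatrix,
    generating_parameters,
    simulate_condition,
)


@pytest.fixture(scope="session")
def q3_12():
    return build_qmatrix(3, 12)


@pytest.fixture(scope="session")
def dina_bundle_small():
    """A small DINA dataset (N=200, 12 items, 3 attributes, BR 0.5)."""
    cond = DesignCondition(200, 12, 3, 0.50, "DINA")
    return simulate_condition(cond, np.random.default_rng(42), seed=42)


@pytest.fixture(scope="session")
def fast_fit_config():
    """Reduced multi-start settings for test-sized fits."""
    return FitConfig(n_starts=4, n_survivors=2, short_iters=8, seed=0)


@pytest.fixture(scope="session")
def generating_params_12(q3_12):
    spec = assign_item_models(q3_12, "LCDMREDUCED")
    return spec, generating_parameters(q3_12, spec)
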