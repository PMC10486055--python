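import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from immucluster.synthetic import simulate_reference_panel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """Default synthetic reference panel (6 immune + 6 non-immune types)."""
    return simulate_reference_panel(seed=11)


@pytest.fixture(scope="session")
def immune_genesets(panel):
    """Planted marker genesets for the six immune cell types."""
    return {ct: sorted(panel.truth_markers[ct]) for ct in panel.immune_columns}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_expr(rng):
    """Random 50-gene x 4-sample expression matrix."""
    data = rng.lognormal(1.0, 1.0, size=(50, 4))
    return pd.DataFrame(data, index=[f"g{i}" for i in range(50)],
                        columns=[f"s{j}" for j in range(4)])
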