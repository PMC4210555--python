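import numpy as np
import pytest

from ecmlm import (
    PanelSpec,
    loiselle_kinship,
    simulate_panel,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def family_panel():
    """Structured benchmark panel: 2 subpops x 10 families x 5 sibs, m=500."""
    spec = PanelSpec(seed=5)
    g, K_true = simulate_panel(spec)
    y = simulate_phenotype(g, K_true, h2=0.5, seed=5)
    return g, K_true, y


@pytest.fixture(scope="session")
def family_kinship(family_panel):
    g, _, _ = family_panel
    return loiselle_kinship(g)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
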