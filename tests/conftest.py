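import numpy as np
import pandas as pd
import pytest

from m6apattern import SimulationConfig, generate_cohort
from m6apattern.data_model import ExpressionMatrix


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale cohort: 60 samples, 300 genes, seconds to generate."""
    base = dict(
        n_samples=60, n_genes=300, n_deg_per_contrast=20, n_prognostic=20,
        n_immune_sets=3, immune_set_size=8, n_pathway_sets=2, pathway_set_size=8,
        seed=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions (n=300, 2000 genes, seed 42)."""
    return generate_cohort(SimulationConfig(seed=42))


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(rng.normal(8, 1, (20, 6)),
                        index=[f"G{i}" for i in range(20)],
                        columns=[f"S{i}" for i in range(6)])
    return ExpressionMatrix(vals)
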