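import numpy as np
import pytest

from mirisk.datamodel import ExpressionMatrix, Scale
from mirisk.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_mirna_probes=150,
        n_mrna_probes=300,
        n_mm=40,
        n_mgus=5,
        n_bmpc=8,
        n_hmcl=8,
        noise_sd=0.6,
        n_survival=36,
        n_validation=60,
        n_de_probes=12,
        n_target_links=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(5)
    values = rng.normal(9.0, 1.0, size=(20, 8))
    return ExpressionMatrix(
        [f"p{i:02d}" for i in range(20)],
        [f"s{j}" for j in range(8)],
        values,
        Scale.LOG2,
    )
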