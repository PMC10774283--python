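import numpy as np
import pandas as pd
import pytest

from mbstage import synthetic


@pytest.fixture(scope="session")
def cell_data():
    return synthetic.generate_cell_data(n_cells_per_cluster=50, n_genes=200,
                                        n_markers_per_cluster=10, effect=3.0,
                                        noise_sd=0.5, seed=1)


@pytest.fixture(scope="session")
def stage_signatures():
    """Five 20-gene stage signatures over a 200-gene universe."""
    return {s: [f"{s}_g{i:02d}" for i in range(20)] for s in synthetic.STAGES}


@pytest.fixture(scope="session")
def planted_cohort(stage_signatures):
    return synthetic.generate_cohort(
        n_samples=60, subtype_props={"S1": 0.5, "S2": 0.5},
        signatures=stage_signatures, effects={("S1", "cyclingGCP"): 2.0},
        noise_sd=1.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_expression(rng):
    genes = [f"g{i:02d}" for i in range(12)]
    samples = [f"s{i}" for i in range(6)]
    return pd.DataFrame(rng.normal(size=(12, 6)), index=genes, columns=samples)
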