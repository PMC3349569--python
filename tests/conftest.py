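import numpy as np
import pytest

from coremod import ExpressionDataset, SimulationConfig, simulate_study


def make_dataset(values, labels, name="toy", genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = [f"s{j+1}" for j in range(values.shape[1])]
    return ExpressionDataset(genes, samples, values, np.asarray(labels), name=name)


@pytest.fixture(scope="session")
def small_study():
    """Three small cohorts with 3 planted driver pathways and private passengers."""
    cfg = SimulationConfig(
        n_cohorts=3, n_genes=300, samples_per_cohort=60, n_pathways=15,
        pathway_size_range=(8, 12), n_driver_pathways=3, driver_effect=1.0,
        driver_member_count=4, n_passenger_degs_per_cohort=10,
        passenger_effect=1.0, seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture
def toy_ds():
    """4 genes x 6 samples, 3 cases then 3 controls, with clear structure."""
    rng = np.random.default_rng(5)
    base = rng.normal(size=(4, 6)) * 0.1
    base[0, :3] += 3.0   # strongly up in cases
    base[1, :3] += 2.0   # up in cases
    base[2, :3] -= 2.5   # down in cases
    return make_dataset(base, [1, 1, 1, -1, -1, -1])
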