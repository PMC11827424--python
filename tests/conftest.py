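import numpy as np
import pandas as pd
import pytest

from tlsquant.pipeline import RunConfig, run_pipeline
from tlsquant.synthetic import CohortConfig, generate_cohort


def small_config(**overrides) -> CohortConfig:
    """A compact cohort: quick to generate, every stage still exercised."""
    defaults = dict(
        n_patients=4,
        domain_count_range=(3, 8),
        tissue_size_um=4000.0,
        seed=11,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    config = small_config()
    datasets, truth = generate_cohort(config)
    return config, datasets, truth


@pytest.fixture(scope="session")
def small_section(small_cohort):
    _, datasets, truth = small_cohort
    return datasets[0], truth.sections[0]


@pytest.fixture(scope="session")
def small_run(small_cohort):
    config, datasets, _ = small_cohort
    return run_pipeline(datasets, RunConfig(seed=config.seed))


def random_cells(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random marker table (all 32 combinations reachable)."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n)],
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "cd20": rng.random(n) < 0.3,
            "cd3": rng.random(n) < 0.5,
            "cd8": rng.random(n) < 0.4,
            "foxp3": rng.random(n) < 0.2,
            "ki67": rng.random(n) < 0.3,
        }
    )
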