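import numpy as np
import pytest

from toxpisim.data_io import ChemAssayMatrix
from toxpisim.synthetic_data import SyntheticConfig, generate


@pytest.fixture
def small_matrix() -> ChemAssayMatrix:
    """3x3 with a known missing pattern (NaN at (0,1) and (2,2))."""
    values = np.array(
        [
            [1.0, np.nan, 2.0],
            [0.0, 3.0, 1.0],
            [2.0, 1.0, np.nan],
        ]
    )
    return ChemAssayMatrix(["c1", "c2", "c3"], ["a1", "a2", "a3"], values)


@pytest.fixture
def synthetic_pair():
    """A seeded masked matrix with its complete ground truth."""
    config = SyntheticConfig(
        n_chemicals=50,
        n_sources=4,
        assays_per_source_range=(10, 10),
        latent_rank=2,
        inactive_fraction=0.3,
        chem_missing_range=(0.1, 0.5),
        seed=11,
    )
    return generate(config)


def random_masked_matrix(
    rng: np.random.Generator,
    n_chem: int = 10,
    n_assay: int = 8,
    missing_fraction: float = 0.25,
    zero_fraction: float = 0.3,
) -> ChemAssayMatrix:
    """Uniform random non-negative matrix with MCAR masking, for oracle suites.

    Guarantees at least one observed value per column.
    """
    values = rng.uniform(0.0, 3.0, size=(n_chem, n_assay))
    values[rng.random(values.shape) < zero_fraction] = 0.0
    mask = rng.random(values.shape) < missing_fraction
    for j in range(n_assay):
        if mask[:, j].all():
            mask[rng.integers(n_chem), j] = False
    values[mask] = np.nan
    return ChemAssayMatrix(
        [f"c{i}" for i in range(n_chem)], [f"a{j}" for j in range(n_assay)], values
    )
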