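import numpy as np
import pytest

from lesionssl import PhantomConfig, generate_cohort

# All training-capable fixtures use a 16x24x24 grid: big enough for
# multi-voxel lesions at 1 mm spacing, small enough for CPU training.
GRID = (16, 24, 24)


@pytest.fixture(scope="session")
def small_cohort():
    """Partially annotated cohort: 12 cases, half positive, half of those masked."""
    return generate_cohort(PhantomConfig(
        n_cases=12, grid_shape=GRID, prevalence=0.5, human_label_fraction=0.5,
        contrast=4.0, seed=42))


@pytest.fixture(scope="session")
def annotated_cohort():
    """Fully annotated cohort for evaluation tests."""
    return generate_cohort(PhantomConfig(
        n_cases=10, grid_shape=GRID, prevalence=0.5, human_label_fraction=1.0,
        contrast=4.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
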