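import numpy as np
import pytest

from maizefusion import FieldConfig, generate_field
from maizefusion.ground_filter import csf_ground, remove_ground


@pytest.fixture(scope="session")
def small_field():
    """2x4-plant field at mid growth, moderate density (shared, read-only)."""
    cfg = FieldConfig(n_rows=2, plants_per_row=4, growth_stage=0.5,
                      point_density=3000, seed=1)
    return generate_field(cfg)


@pytest.fixture(scope="session")
def separated_field():
    """3x4-plant field at an early stage: canopies do not touch."""
    cfg = FieldConfig(n_rows=3, plants_per_row=4, growth_stage=0.3,
                      point_density=3000, seed=1)
    return generate_field(cfg)


@pytest.fixture(scope="session")
def canopy_and_truth(small_field):
    """Ground-free canopy of the small field plus its truth labels."""
    cls = csf_ground(small_field.cloud)
    return remove_ground(small_field.cloud, cls), small_field


@pytest.fixture
def rng():
    return np.random.default_rng(42)
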