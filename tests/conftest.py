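import numpy as np
import pytest

from stdcl.data import SpatialDataset
from stdcl.simulate import TissueSpec, generate_dataset


@pytest.fixture
def tiny_dataset() -> SpatialDataset:
    """3 spots x 2 genes, hand-written."""
    return SpatialDataset(
        counts=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        spot_ids=["s1", "s2", "s3"],
        gene_ids=["g1", "g2"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
    )


@pytest.fixture(scope="session")
def small_tissue() -> SpatialDataset:
    """A fast 200-spot, 60-gene striped tissue for pipeline-level tests."""
    spec = TissueSpec(
        n_spots=200, n_genes=60, n_domains=3, n_markers_per_domain=8,
        marker_log_fc=1.5, seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
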