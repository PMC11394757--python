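import numpy as np
import pytest

import pocketgnn as pg
from pocketgnn.graphs import GraphConfig
from pocketgnn.pipeline import SurfaceConfig, encode_synthetic


@pytest.fixture(scope="session")
def small_structure():
    """One deterministic planted-pocket structure."""
    spec = pg.SyntheticSpec(n_structures=12, seed=11)
    return pg.make_blob_structure(spec, 0)


@pytest.fixture(scope="session")
def small_encoding(small_structure):
    """Encoded at the scaled-down benchmark geometry."""
    return encode_synthetic(small_structure,
                            SurfaceConfig(target_density=0.6),
                            GraphConfig(voxel_size=2.0))


@pytest.fixture(scope="session")
def small_model():
    return pg.PointGNNModel(seed=3, config=GraphConfig(voxel_size=2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
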