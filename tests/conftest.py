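import numpy as np
import pytest

import seqspace as ss
from seqspace.synthetic import ClusteredSpec, clustered_msa


@pytest.fixture
def toy_alignment():
    return ss.Alignment(("s1", "s2", "s3"), ("ACDE", "AC-E", "AADE"))


@pytest.fixture(scope="session")
def hierarchical_fixture():
    """The canonical 4-group / 12-sub-family clustered alignment with its
    fitted 3-component embedding (generator defaults, seed 42)."""
    fx = clustered_msa(ClusteredSpec(seed=42))
    D = ss.active_distance_matrix(fx.alignment)
    model = ss.fit_mds(D)
    return fx, model


@pytest.fixture
def euclidean_cloud():
    """Random 3-D point configuration and its exact squared-distance matrix."""
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(25, 3))
    diff = pts[:, None, :] - pts[None, :, :]
    return pts, (diff**2).sum(axis=2)
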