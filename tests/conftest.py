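import numpy as np
import pytest

import brushcyto as bc


@pytest.fixture(scope="session")
def benign_cluster():
    """One rendered benign cluster with ground truth."""
    return bc.render_cluster(bc.benign_preset(), seed=101, cluster_id="b101")


@pytest.fixture(scope="session")
def malignant_cluster():
    return bc.render_cluster(bc.malignant_preset(), seed=202, cluster_id="m202")


@pytest.fixture(scope="session")
def preprocessed_benign(benign_cluster):
    return bc.preprocess_cluster(benign_cluster.as_cluster_image())


@pytest.fixture(scope="session")
def two_disc_mask():
    """Two discs of radius 20 px overlapping by 8 px along the x axis."""
    mask = np.zeros((80, 120), dtype=bool)
    yy, xx = np.ogrid[:80, :120]
    for cy, cx in ((40, 40), (40, 72)):  # centre distance 32 = 2*20 - 8
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 20**2
    return mask
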