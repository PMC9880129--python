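import numpy as np
import pytest
from scipy import ndimage

import dce4dreg as d


@pytest.fixture(scope="session")
def default_phantom():
    """Default study-condition phantom (4 mm smooth motion, 2% noise)."""
    return d.generate_phantom(d.PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def clean_phantom():
    """Motion- and noise-free phantom (ground-truth physiology only)."""
    return d.generate_phantom(
        d.PhantomConfig(seed=0, motion_mode="none", noise_sigma=0.0))


@pytest.fixture()
def smooth_series():
    """Small smooth random 4D series for transform/metric unit tests."""
    rng = np.random.default_rng(7)
    vox = ndimage.gaussian_filter(rng.uniform(0, 100, (12, 12, 6, 4)),
                                  (1.5, 1.5, 1.5, 0))
    return d.DceSeries(voxels=vox, spacing=(1.0, 1.0, 1.5),
                       times=[0.0, 90.0, 160.0, 230.0])
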