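import numpy as np
import pytest

from fundusseg.data import SyntheticFundusParams, generate_synthetic_fundus


@pytest.fixture(scope="session")
def synthetic_sample():
    """One deterministic synthetic fundus image with mask and disc centre."""
    return generate_synthetic_fundus(SyntheticFundusParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def disc_mask(size=101, center=(50, 50), disc_radius=40, cup_radius=20):
    """Concentric filled-circle mask: 0 background, 1 disc, 2 cup."""
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[r2 <= disc_radius ** 2] = 1
    if cup_radius:
        mask[r2 <= cup_radius ** 2] = 2
    return mask
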