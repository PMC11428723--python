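import numpy as np
import pytest

from stepreg import SynthConfig, make_pair


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_case():
    """One deterministic annotated case on a small grid, shared read-only."""
    cfg = SynthConfig(shape=(24, 24, 12), n_blobs=20, field_amplitude=1.5,
                      field_smoothness=4.0, cavity_radius=3.0, noise_sd=0.005,
                      n_landmarks=6, seed=7)
    return make_pair(cfg)


@pytest.fixture()
def smooth_field(rng):
    """A smooth random displacement field on a 12x10x8 grid, < 1 voxel."""
    from scipy.ndimage import gaussian_filter

    u = np.stack([gaussian_filter(rng.standard_normal((12, 10, 8)), 2.0)
                  for _ in range(3)])
    u *= 0.8 / np.abs(u).max()
    from stepreg import DisplacementField

    return DisplacementField(u)
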