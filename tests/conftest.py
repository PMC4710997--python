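from dataclasses import dataclass

import numpy as np
import pytest

import dwidenoise_sr as dsr


@dataclass
class Phantom:
    field: dsr.TensorField
    scheme: dsr.GradientScheme
    clean: dsr.DWISequence
    sigma: float

    def noisy(self, seed: int) -> dsr.DWISequence:
        return dsr.add_rician_noise(self.clean, self.sigma, seed=seed)


@pytest.fixture(scope="session")
def standard_phantom() -> Phantom:
    """The reference simulation design: two-region tensor field, 64x64x5
    voxels, 1 b=0 volume + 32 directions at b=1000 s/mm^2, sigma = 1/10 of
    the mean central b=0 intensity."""
    field = dsr.make_tensor_field((64, 64, 5), "two_region", seed=1)
    scheme = dsr.make_gradient_scheme(n_directions=32, b_value=1000.0)
    clean = dsr.simulate_dwi(field, scheme, s0=100.0)
    sigma = dsr.b0_center_noise_level(clean)
    return Phantom(field=field, scheme=scheme, clean=clean, sigma=sigma)


@pytest.fixture(scope="session")
def small_phantom() -> Phantom:
    """A fast variant for pipeline-shape tests: 32x32x4, 12 directions."""
    field = dsr.make_tensor_field((32, 32, 4), "two_region", seed=2)
    scheme = dsr.make_gradient_scheme(n_directions=12, b_value=1000.0)
    clean = dsr.simulate_dwi(field, scheme, s0=100.0)
    sigma = dsr.b0_center_noise_level(clean)
    return Phantom(field=field, scheme=scheme, clean=clean, sigma=sigma)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
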