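import numpy as np
import pytest

from cineraki.phantom import PhantomConfig, generate_cine_truth, make_coil_sensitivities
from cineraki.sampling import SamplingScheme, build_mask
from cineraki.transforms import fft2c, sos_combine


@pytest.fixture(scope="session")
def small_truth():
    """3-slice, 4-phase, 4-coil noise-free phantom at 64x64."""
    cfg = PhantomConfig(ny=64, nx=64, n_slices=3, n_phases=4, n_coils=4, noise_std=0.0, seed=11)
    return generate_cine_truth(cfg)


@pytest.fixture(scope="session")
def mask_r4():
    return build_mask(SamplingScheme(R=4, n_acs=26, ny=64))


def bandlimited_frame(ny=32, nx=32, n_coils=8, margin=6, noise_std=0.0, seed=7):
    """Single multi-coil frame whose linear interpolation model is exactly
    realizable: 3x3-bandlimited coil sensitivities times an object whose
    spectrum is zero within ``margin`` of the k-space border (so zero-padded
    boundary handling is exact). Returns (kspace, reference SoS image)."""
    rng = np.random.default_rng(seed)
    ospec = np.zeros((ny, nx), complex)
    core = (
        rng.standard_normal((ny - 2 * margin, nx - 2 * margin))
        + 1j * rng.standard_normal((ny - 2 * margin, nx - 2 * margin))
    )
    ospec[margin : ny - margin, margin : nx - margin] = core
    from cineraki.transforms import ifft2c

    obj = ifft2c(ospec)
    prof = make_coil_sensitivities(n_coils, ny, nx, bandlimit=3, seed=1).profiles
    coil_images = prof * obj
    k = fft2c(coil_images)
    if noise_std > 0:
        k = k + noise_std * np.abs(k).max() * (
            rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
        ) / np.sqrt(2)
    return k, sos_combine(coil_images)


@pytest.fixture(scope="session")
def bandlimited_32():
    return bandlimited_frame()
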