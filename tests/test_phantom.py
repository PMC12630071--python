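import numpy as np
import pytest

from cineraki.phantom import (
    PhantomConfig,
    ROI,
    generate_cine_truth,
    heart_roi,
    make_coil_sensitivities,
)
from cineraki.transforms import fft2c, ifft2c, sos_combine


class TestCoilSensitivities:
    def test_uniform_single_coil_is_one(self):
        prof = make_coil_sensitivities(1, 48, 48, slice_drift=0.0, uniform=True).profiles
        assert np.array_equal(prof, np.ones((1, 48, 48), complex))

    def test_same_seed_reproducible(self):
        a = make_coil_sensitivities(4, 48, 48, slice_index=2, slice_drift=0.1, seed=3)
        b = make_coil_sensitivities(4, 48, 48, slice_index=2, slice_drift=0.1, seed=3)
        assert np.array_equal(a.profiles, b.profiles)

    def test_bandlimit_confines_spectrum(self):
        prof = make_coil_sensitivities(4, 32, 32, bandlimit=3, seed=1).profiles
        spec = fft2c(prof)
        total = np.sum(np.abs(spec) ** 2)
        core = np.sum(np.abs(spec[:, 15:18, 15:18]) ** 2)
        assert (total - core) / total < 1e-10

    def test_slice_difference_monotone_in_drift(self):
        diffs = []
        for drift in (0.0, 0.05, 0.1, 0.2):
            a = make_coil_sensitivities(4, 48, 48, slice_index=0, slice_drift=drift, seed=3)
            b = make_coil_sensitivities(4, 48, 48, slice_index=1, slice_drift=drift, seed=3)
            diffs.append(np.mean(np.abs(a.profiles - b.profiles)))
        assert diffs[0] == 0.0
        assert all(d1 > d0 for d0, d1 in zip(diffs, diffs[1:]))

    def test_sos_strictly_positive(self):
        prof = make_coil_sensitivities(6, 48, 48, seed=0).profiles
        assert sos_combine(prof).min() > 0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            make_coil_sensitivities(0, 32, 32)
        with pytest.raises(ValueError):
            make_coil_sensitivities(2, 32, 32, bandlimit=4)


class TestCineTruth:
    def test_shape_contract(self):
        cfg = PhantomConfig(ny=96, nx=96, n_slices=3, n_phases=4, n_coils=8, noise_std=0.0)
        t = generate_cine_truth(cfg)
        assert t.kspace.shape == (3, 4, 8, 96, 96)
        assert t.sos_images.shape == (3, 4, 96, 96)

    def test_noise_free_fourier_round_trip(self, small_truth):
        err = np.max(np.abs(ifft2c(small_truth.kspace) - small_truth.coil_images))
        assert err < 1e-10

    def test_parseval(self, small_truth):
        e_k = np.sum(np.abs(small_truth.kspace) ** 2)
        e_i = np.sum(np.abs(small_truth.coil_images) ** 2)
        assert abs(e_k - e_i) / e_k < 1e-8

    def test_phase_changes_confined_to_heart_disc(self, small_truth):
        cfg = small_truth.config
        cy, cx = cfg.center
        yy, xx = np.mgrid[0 : cfg.ny, 0 : cfg.nx]
        outside = (yy - cy) ** 2 + (xx - cx) ** 2 > (cfg.heart_radius_range[1] + 1) ** 2
        sos = small_truth.sos_images
        for p in range(1, cfg.n_phases):
            diff = np.abs(sos[:, p] - sos[:, 0])
            assert np.max(diff[:, outside]) < 1e-12

    def test_phase_constant_coil_profiles(self, small_truth):
        # ratio of coil images across phases equals 1 where the anatomy is static
        ci = small_truth.coil_images
        assert np.allclose(
            ci[:, 1, :, :10, :10], ci[:, 0, :, :10, :10], atol=1e-12
        )

    def test_slice_drift_increases_with_distance_from_middle(self):
        cfg = PhantomConfig(ny=64, nx=64, n_slices=5, n_phases=1, n_coils=4, noise_std=0.0, slice_drift=0.2)
        t = generate_cine_truth(cfg)
        mid = 2
        d = [np.mean(np.abs(t.coil_images[s, 0] - t.coil_images[mid, 0])) for s in range(5)]
        assert d[0] > d[1] > d[2] == 0.0
        assert d[4] > d[3] > d[2]

    def test_noise_statistics(self):
        cfg = PhantomConfig(ny=64, nx=64, n_slices=1, n_phases=2, n_coils=4, noise_std=0.01, seed=1)
        t = generate_cine_truth(cfg)
        noise = t.kspace - fft2c(t.coil_images)
        ref = np.abs(fft2c(t.coil_images)).max()
        measured = np.std(noise) / ref
        assert 0.008 < measured < 0.012


class TestHeartROI:
    def test_centered_roi_is_70_wide(self):
        cfg = PhantomConfig(ny=96, nx=96, heart_center=(48, 48))
        roi = heart_roi(cfg)
        assert (roi.row_start, roi.row_stop) == (13, 83)
        assert (roi.col_start, roi.col_stop) == (13, 83)

    def test_edge_center_clipped(self):
        cfg = PhantomConfig(ny=96, nx=96, heart_center=(10, 48))
        roi = heart_roi(cfg)
        assert (roi.row_start, roi.row_stop) == (0, 45)
        assert (roi.col_start, roi.col_stop) == (13, 83)

    @pytest.mark.parametrize("center", [(0, 48), (95, 0), (48, 95), (32, 32)])
    def test_area_never_exceeds_70x70(self, center):
        cfg = PhantomConfig(ny=96, nx=96, heart_center=center)
        roi = heart_roi(cfg)
        h, w = roi.shape
        assert 0 < h * w <= 70 * 70

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(ny=16, nx=96)
        with pytest.raises(ValueError):
            PhantomConfig(heart_center=(200, 48))
        with pytest.raises(ValueError):
            PhantomConfig(noise_std=-1.0)
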