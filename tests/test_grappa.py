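import numpy as np
import pytest

from cineraki.grappa import (
    CalibrationError,
    GrappaKernelSpec,
    GrappaReconstructor,
    grappa_apply,
    grappa_calibrate,
)
from cineraki.sampling import SamplingScheme, build_mask, extract_acs, undersample
from cineraki.transforms import ifft2c, sos_combine
from cineraki.metrics import nmse, psnr


def brute_force_apply(weights, zero_filled, mask):
    """Independent per-target-pixel reference: explicit loops re-derive the
    source geometry and accumulate each target with one dot product."""
    nc, ny, nx = zero_filled.shape
    spec = weights.spec
    out = zero_filled.copy()
    half_kx = spec.kx_taps // 2
    for r in range(ny):
        if mask.acquired[r]:
            continue
        d = (r - mask.lattice_offset) % spec.R
        w = weights.weights[d]
        for x in range(nx):
            svec = np.zeros(spec.n_unknowns(nc), complex)
            i = 0
            for c in range(nc):
                for j in range(spec.n_source_lines):
                    row = r - d + (j - spec.center_source) * spec.R
                    for t in range(-half_kx, half_kx + 1):
                        col = x + t
                        if 0 <= row < ny and 0 <= col < nx:
                            svec[i] = zero_filled[c, row, col]
                        i += 1
            for c in range(nc):
                out[c, r, x] = np.dot(svec, w[:, c])
    return out


class TestCalibration:
    def test_recovers_exact_interpolator_of_linear_model(self):
        """When the data follow an exact shift-invariant linear model
        (bandlimited coil mixing), calibration on one object recovers
        weights that exactly interpolate data from a *different* object
        through the same model."""
        from conftest import bandlimited_frame

        k_a, _ = bandlimited_frame(seed=7)
        k_b, _ = bandlimited_frame(seed=8)
        mask = build_mask(SamplingScheme(R=2, n_acs=20, ny=32))
        w = grappa_calibrate(extract_acs(k_a, mask), GrappaKernelSpec(R=2), ridge=0.0)
        filled_b = grappa_apply(w, undersample(k_b, mask), mask)
        scale = np.max(np.abs(k_b))
        assert np.max(np.abs(filled_b - k_b)) < 1e-8 * scale

    def test_unknown_count(self):
        spec = GrappaKernelSpec(R=4)
        assert spec.n_unknowns(8) == 8 * 5 * 5

    def test_duplicated_coil_with_ridge_is_finite(self):
        rng = np.random.default_rng(0)
        acs = rng.standard_normal((2, 24, 16)) + 1j * rng.standard_normal((2, 24, 16))
        acs = np.concatenate([acs, acs], axis=0)  # rank-deficient coil pair
        w0 = grappa_calibrate(acs, GrappaKernelSpec(R=2), ridge=0.0)  # min-norm
        w1 = grappa_calibrate(acs, GrappaKernelSpec(R=2), ridge=1e-6)
        for d in w1.weights:
            assert np.all(np.isfinite(w0.weights[d]))
            assert np.all(np.isfinite(w1.weights[d]))

    def test_too_small_acs_rejected(self):
        rng = np.random.default_rng(0)
        acs = rng.standard_normal((2, 6, 16)) + 1j * rng.standard_normal((2, 6, 16))
        with pytest.raises(CalibrationError):
            grappa_calibrate(acs, GrappaKernelSpec(R=4))

    def test_all_zero_acs_rejected(self):
        with pytest.raises(CalibrationError):
            grappa_calibrate(np.zeros((2, 24, 16), complex), GrappaKernelSpec(R=2))


class TestApply:
    def test_exact_recovery_and_bit_identity_to_brute_force(self, bandlimited_32):
        # bandlimited sensitivities (3x3 support) at R=2: the linear model is
        # exactly realizable, so GRAPPA recovers the missing lines to
        # numerical precision.
        k, ref = bandlimited_32
        mask = build_mask(SamplingScheme(R=2, n_acs=20, ny=32))
        zf = undersample(k, mask)
        w = grappa_calibrate(extract_acs(k, mask), GrappaKernelSpec(R=2), ridge=0.0)
        filled = grappa_apply(w, zf, mask)
        est = sos_combine(ifft2c(filled))
        assert nmse(ref, est) < 1e-6
        assert psnr(ref, est) > 100
        oracle = brute_force_apply(w, zf, mask)
        assert np.array_equal(filled, oracle)

    def test_r1_is_identity(self):
        rng = np.random.default_rng(1)
        k = rng.standard_normal((2, 16, 12)) + 1j * rng.standard_normal((2, 16, 12))
        mask = build_mask(SamplingScheme(R=1, n_acs=4, ny=16))
        w = grappa_calibrate(k[:, 2:14], GrappaKernelSpec(R=1))
        assert np.array_equal(grappa_apply(w, k, mask), k)

    def test_acquired_rows_untouched(self, bandlimited_32):
        k, _ = bandlimited_32
        mask = build_mask(SamplingScheme(R=2, n_acs=20, ny=32))
        zf = undersample(k, mask)
        w = grappa_calibrate(extract_acs(k, mask), GrappaKernelSpec(R=2))
        filled = grappa_apply(w, zf, mask)
        assert np.array_equal(filled[:, mask.acquired], zf[:, mask.acquired])

    def test_linearity(self, bandlimited_32):
        k, _ = bandlimited_32
        mask = build_mask(SamplingScheme(R=2, n_acs=20, ny=32))
        zf = undersample(k, mask)
        w = grappa_calibrate(extract_acs(k, mask), GrappaKernelSpec(R=2))
        alpha = 1.7 - 0.3j
        a = grappa_apply(w, alpha * zf, mask)
        b = alpha * grappa_apply(w, zf, mask)
        assert np.max(np.abs(a - b)) < 1e-10 * np.max(np.abs(b))

    def test_r_mismatch_rejected(self, bandlimited_32):
        k, _ = bandlimited_32
        mask2 = build_mask(SamplingScheme(R=2, n_acs=20, ny=32))
        mask3 = build_mask(SamplingScheme(R=4, n_acs=12, ny=32))
        w = grappa_calibrate(extract_acs(k, mask2), GrappaKernelSpec(R=2))
        with pytest.raises(ValueError):
            grappa_apply(w, undersample(k, mask3), mask3)


class TestReconstructor:
    def test_fully_sampled_equals_reference(self, bandlimited_32):
        k, ref = bandlimited_32
        mask = build_mask(SamplingScheme(R=1, n_acs=20, ny=32))
        rec = GrappaReconstructor().fit(k, mask)
        assert np.allclose(rec.reconstruct(k), ref, atol=1e-12)

    def test_sklearn_params_round_trip(self):
        rec = GrappaReconstructor(ridge=1e-4)
        assert rec.get_params()["ridge"] == 1e-4
        rec.set_params(kx_taps=3)
        assert rec.kx_taps == 3

    def test_estimator_matches_functions(self, bandlimited_32):
        k, ref = bandlimited_32
        mask = build_mask(SamplingScheme(R=2, n_acs=20, ny=32))
        rec = GrappaReconstructor(ridge=0.0).fit(k, mask)
        est = rec.reconstruct(k)
        assert nmse(ref, est) < 1e-6
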