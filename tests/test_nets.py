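import numpy as np
import pytest

from cineraki.nets import (
    LayerSpec,
    SrakiReconstructor,
    TrainingError,
    TrainingHyper,
    WeightSet,
    apply_network,
    build_network,
    count_parameters,
    make_training_pair,
    train_network,
)
from cineraki.sampling import SamplingScheme, build_mask, extract_acs, undersample
from cineraki.transforms import NormalizationRecord, split_complex


class TestArchitecture:
    @pytest.mark.parametrize(
        "method,expected",
        [("sraki", 22530), ("raki", 58814), ("rraki", 81344)],
    )
    def test_parameter_counts_at_15_coils(self, method, expected):
        assert count_parameters(build_network(method, 15)) == expected

    def test_rraki_is_sum_of_paths(self):
        n = count_parameters(build_network("raki", 15)) + count_parameters(
            build_network("sraki", 15)
        )
        assert count_parameters(build_network("rraki", 15)) == n

    def test_sraki_single_coil(self):
        assert count_parameters(build_network("sraki", 1)) == 2 * 2 * 25 + 2

    def test_channel_contract(self):
        for method in ("sraki", "raki", "rraki"):
            spec = build_network(method, 7)
            assert spec.layers[0].in_channels == 14
            assert spec.layers[-1].out_channels == 14

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            build_network("grappanet", 4)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            LayerSpec(2, 2, 4, 5)


class TestTrainingPair:
    def test_r1_input_equals_target(self):
        rng = np.random.default_rng(0)
        acs = rng.standard_normal((2, 12, 16)) + 1j * rng.standard_normal((2, 12, 16))
        mask = build_mask(SamplingScheme(R=1, n_acs=12, ny=32))
        pair = make_training_pair(acs, mask, build_network("sraki", 2))
        assert np.array_equal(pair.input, pair.target)

    def test_zeroed_row_fraction(self):
        rng = np.random.default_rng(0)
        mask = build_mask(SamplingScheme(R=4, n_acs=26, ny=64))
        acs = rng.standard_normal((2, 26, 16)) + 1j * rng.standard_normal((2, 26, 16))
        pair = make_training_pair(acs, mask, build_network("sraki", 2))
        zero_rows = np.all(pair.input == 0, axis=(0, 2)).sum()
        assert abs(zero_rows / 26 - 3 / 4) < 0.1

    def test_raki_valid_region_on_26_rows(self):
        rng = np.random.default_rng(0)
        mask = build_mask(SamplingScheme(R=4, n_acs=26, ny=64))
        acs = rng.standard_normal((2, 26, 20)) + 1j * rng.standard_normal((2, 26, 20))
        pair = make_training_pair(acs, mask, build_network("raki", 2))
        assert pair.valid_rows == slice(3, 23)
        assert pair.valid_cols == slice(3, 17)

    def test_too_small_acs_rejected(self):
        rng = np.random.default_rng(0)
        mask = build_mask(SamplingScheme(R=4, n_acs=26, ny=64))
        acs = rng.standard_normal((2, 4, 16)) + 1j * rng.standard_normal((2, 4, 16))
        with pytest.raises(TrainingError):
            make_training_pair(acs, mask, build_network("raki", 2))


def small_pair(method="sraki", nc=2, n_acs=14, nx=16, R=2, seed=0):
    rng = np.random.default_rng(seed)
    mask = build_mask(SamplingScheme(R=R, n_acs=n_acs, ny=48))
    acs = rng.standard_normal((nc, n_acs, nx)) + 1j * rng.standard_normal((nc, n_acs, nx))
    spec = build_network(method, nc)
    return spec, make_training_pair(acs, mask, spec), mask


class TestTraining:
    def test_r1_identity_is_realizable(self):
        spec, pair, _ = small_pair(R=1)
        ws = train_network(spec, pair, TrainingHyper(epochs=300, seed=0))
        assert ws.final_loss < 1e-3

    def test_bit_identical_given_seed(self):
        spec, pair, _ = small_pair()
        a = train_network(spec, pair, TrainingHyper(epochs=40, seed=5))
        b = train_network(spec, pair, TrainingHyper(epochs=40, seed=5))
        assert np.array_equal(a.flatten(), b.flatten())
        assert np.array_equal(a.loss_trace, b.loss_trace)

    def test_running_minimum_of_loss_trace_non_increasing(self):
        spec, pair, _ = small_pair()
        ws = train_network(spec, pair, TrainingHyper(epochs=150, seed=1))
        run_min = np.minimum.accumulate(ws.loss_trace)
        assert np.all(np.diff(run_min) <= 0)

    def test_rraki_reported_loss_is_combined(self):
        spec, pair, _ = small_pair("rraki")
        hyper = TrainingHyper(epochs=30, lambda_combine=1.0, seed=2)
        ws = train_network(spec, pair, hyper)
        # recompute MAE(sum, target) + MAE(linear, target) at final weights
        from cineraki.nets import _Conv, _forward_path

        main = [_Conv(s, W, b) for s, (W, b) in zip(spec.layers, ws.layers)]
        lin = [_Conv(s, W, b) for s, (W, b) in zip(spec.linear_layers, ws.linear_layers)]
        y_lin = _forward_path(lin, pair.input)
        y = _forward_path(main, pair.input) + y_lin
        vr, vc = pair.valid_rows, pair.valid_cols
        mae = lambda a: float(np.mean(np.abs((a - pair.target)[:, vr, vc])))
        assert abs(ws.final_loss - (mae(y) + mae(y_lin))) < 1e-10

    def test_raki_trains_and_improves(self):
        spec, pair, _ = small_pair("raki", n_acs=16)
        ws = train_network(spec, pair, TrainingHyper(epochs=120, seed=0))
        assert ws.loss_trace[-1] < ws.loss_trace[0]


class TestApply:
    def test_identity_kernel_passthrough(self):
        nc = 2
        spec = build_network("sraki", nc)
        W = np.zeros((2 * nc, 2 * nc, 5, 5))
        for c in range(2 * nc):
            W[c, c, 2, 2] = 1.0
        ws = WeightSet(
            method="sraki",
            spec=spec,
            layers=((W, np.zeros(2 * nc)),),
            linear_layers=(),
            norm=NormalizationRecord(scale=1.0),
        )
        rng = np.random.default_rng(3)
        k = rng.standard_normal((nc, 32, 16)) + 1j * rng.standard_normal((nc, 32, 16))
        mask = build_mask(SamplingScheme(R=2, n_acs=8, ny=32))
        zf = undersample(k, mask)
        out = apply_network(ws, zf, mask)
        assert np.allclose(out, zf, atol=1e-12)

    def test_output_shape_and_data_consistency(self):
        spec, pair, mask = small_pair()
        ws = train_network(spec, pair, TrainingHyper(epochs=10, seed=0))
        rng = np.random.default_rng(4)
        k = rng.standard_normal((2, 48, 16)) + 1j * rng.standard_normal((2, 48, 16))
        zf = undersample(k, mask)
        out = apply_network(ws, zf, mask)
        assert out.shape == zf.shape
        assert np.array_equal(out[:, mask.acquired], zf[:, mask.acquired])

    def test_sraki_path_linear_when_bias_zero(self):
        spec, pair, mask = small_pair()
        ws = train_network(spec, pair, TrainingHyper(epochs=10, seed=0))
        ws_nobias = WeightSet(
            method="sraki",
            spec=spec,
            layers=((ws.layers[0][0], np.zeros_like(ws.layers[0][1])),),
            linear_layers=(),
            norm=ws.norm,
        )
        from cineraki.nets import _run_weights

        rng = np.random.default_rng(5)
        x = rng.standard_normal((4, 20, 16))
        assert np.allclose(
            _run_weights(ws_nobias, 3.0 * x), 3.0 * _run_weights(ws_nobias, x), atol=1e-10
        )

    def test_coil_mismatch_rejected(self):
        spec, pair, mask = small_pair()
        ws = train_network(spec, pair, TrainingHyper(epochs=5, seed=0))
        with pytest.raises(ValueError):
            apply_network(ws, np.zeros((5, 48, 16), complex), mask)


class TestEstimator:
    def test_fit_transform_reconstruct(self, small_truth, mask_r4):
        rec = SrakiReconstructor(epochs=60, seed=0)
        frame = small_truth.kspace[0, 0]
        rec.fit(frame, mask_r4)
        assert rec.weights_.method == "sraki"
        img = rec.reconstruct(frame)
        assert img.shape == frame.shape[-2:]
        assert np.all(img >= 0)

    def test_get_set_params(self):
        rec = SrakiReconstructor(epochs=10)
        assert rec.get_params()["epochs"] == 10
        rec.set_params(lr=0.5)
        assert rec.lr == 0.5
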