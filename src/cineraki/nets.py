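"""Scan-specific k-space interpolation networks: SRAKI, RAKI and rRAKI.

All three operate on the real 2N-channel packing of a zero-filled complex
k-space frame and predict the complete k-space (same 2N channels):

* **SRAKI** — a single linear 5x5 convolution, 2N -> 2N, with bias.  This is
  the linear path of rRAKI trained on its own; a parallelized GRAPPA analog
  with gradient-descent regularization.
* **RAKI**  — conv 2N->64 (5x5) + ReLU, conv 64->32 (1x1) + ReLU,
  conv 32->2N (3x3), all with bias.
* **rRAKI** — the RAKI stack plus a parallel SRAKI layer; the output is the
  sum of both paths and the loss combines both (weight ``lambda_combine``).

Training is full-batch gradient descent on the ACS only: the input is the
ACS with the rows that fall off the global acquisition lattice zeroed, the
target is the full ACS, and the mean-absolute-error loss is restricted to a
valid region that excludes half the receptive field at each border (to avoid
zero-padding bias).  Optimization is Adam at lr 0.01 for 600 epochs with a
reduce-on-plateau schedule (factor 0.1, patience 10, relative threshold
1e-3).  Everything is float64 numpy with a fixed per-seed initialization
stream, so two runs with the same seed are bit-identical.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .sampling import SamplingMask, extract_acs, undersample
from .transforms import (
    NormalizationRecord,
    data_consistency,
    ifft2c,
    merge_complex,
    normalize_kspace,
    sos_combine,
    split_complex,
)

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainingHyper",
    "TrainingPair",
    "WeightSet",
    "TrainingError",
    "DivergenceError",
    "build_network",
    "count_parameters",
    "make_training_pair",
    "train_network",
    "apply_network",
    "SrakiReconstructor",
    "RakiReconstructor",
    "RrakiReconstructor",
]

METHODS = ("sraki", "raki", "rraki")


class TrainingError(ValueError):
    """The ACS is too small (or degenerate) to train the requested network."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class LayerSpec:
    in_channels: int
    out_channels: int
    kernel_ky: int
    kernel_kx: int
    has_bias: bool = True
    activation: str = "none"  # "relu" or "none"

    def __post_init__(self):
        if self.kernel_ky % 2 != 1 or self.kernel_kx % 2 != 1:
            raise ValueError("kernel dimensions must be odd")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.activation not in ("relu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def n_parameters(self) -> int:
        n = self.in_channels * self.out_channels * self.kernel_ky * self.kernel_kx
        return n + (self.out_channels if self.has_bias else 0)


@dataclass(frozen=True)
class NetworkSpec:
    method: str
    layers: tuple[LayerSpec, ...]
    linear_layers: tuple[LayerSpec, ...]  # parallel linear path (rRAKI), else empty
    n_coils: int

    @property
    def margin(self) -> tuple[int, int]:
        """Half the total receptive field per dimension, over the deeper path."""
        my = max(
            sum(l.kernel_ky - 1 for l in path) // 2
            for path in (self.layers, self.linear_layers)
            if path
        )
        mx = max(
            sum(l.kernel_kx - 1 for l in path) // 2
            for path in (self.layers, self.linear_layers)
            if path
        )
        return my, mx


def build_network(method: str, n_coils: int) -> NetworkSpec:
    """Build the layer geometry of one of the three methods.

    The RAKI hidden widths (64 and 32) follow from the published parameter
    counts at 15 coils: 30*64*25+64 + 64*32+32 + 32*30*9+30 = 58 814.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    m = method.lower()
    n = 2 * n_coils
    sraki_layer = (LayerSpec(n, n, 5, 5, True, "none"),)
    raki_layers = (
        LayerSpec(n, 64, 5, 5, True, "relu"),
        LayerSpec(64, 32, 1, 1, True, "relu"),
        LayerSpec(32, n, 3, 3, True, "none"),
    )
    if m == "sraki":
        return NetworkSpec("sraki", sraki_layer, (), n_coils)
    if m == "raki":
        return NetworkSpec("raki", raki_layers, (), n_coils)
    if m == "rraki":
        return NetworkSpec("rraki", raki_layers, sraki_layer, n_coils)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def count_parameters(spec: NetworkSpec) -> int:
    """Total trainable parameters (weights + biases, both paths for rRAKI)."""
    return sum(l.n_parameters for l in spec.layers) + sum(
        l.n_parameters for l in spec.linear_layers
    )


@dataclass(frozen=True)
class TrainingHyper:
    loss: str = "mae"
    epochs: int = 600
    lr: float = 0.01
    factor: float = 0.1
    patience: int = 10
    threshold: float = 1e-3
    lambda_combine: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.loss != "mae":
            raise ValueError("only the mean-absolute-error loss is supported")
        if self.epochs < 1 or self.lr <= 0:
            raise ValueError("epochs must be >= 1 and lr > 0")
        if self.lambda_combine < 0:
            raise ValueError("lambda_combine must be >= 0")


@dataclass(frozen=True)
class TrainingPair:
    """Normalized (input, target) channel stacks plus the valid loss region."""

    input: np.ndarray  # real [2N, H, W]
    target: np.ndarray  # real [2N, H, W]
    valid_rows: slice
    valid_cols: slice
    norm: NormalizationRecord


@dataclass(frozen=True)
class WeightSet:
    """Trained parameters of one network, with provenance and loss trace."""

    method: str
    spec: NetworkSpec
    layers: tuple  # ((W [out,in,ky,kx], b [out] | None), ...)
    linear_layers: tuple
    norm: NormalizationRecord
    provenance: dict = field(default_factory=dict)
    loss_trace: np.ndarray | None = None

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def flatten(self) -> np.ndarray:
        """All weights then biases, layer by layer, main path then linear."""
        parts = []
        for W, b in tuple(self.layers) + tuple(self.linear_layers):
            parts.append(W.ravel())
            if b is not None:
                parts.append(b.ravel())
        return np.concatenate(parts)


def make_training_pair(
    acs: np.ndarray,
    mask: SamplingMask,
    network: NetworkSpec,
    norm: NormalizationRecord | None = None,
) -> TrainingPair:
    """Build the (zero-filled ACS, full ACS) training pair for one frame.

    Rows of the ACS that do not fall on the global acquisition lattice are
    zeroed in the input (retrospective undersampling restricted to the ACS
    block); the target is the full ACS. Both are scaled by ``norm`` (computed
    from the ACS if not given) and packed into real channel stacks. The
    valid region excludes half the network's receptive field per side.
    """
    acs = np.asarray(acs)
    if acs.ndim != 3:
        raise ValueError("acs must be [n_coils, n_acs, nx]")
    nc, n_acs, nx = acs.shape
    if nc != network.n_coils:
        raise ValueError(f"ACS has {nc} coils, network expects {network.n_coils}")
    my, mx = network.margin
    if n_acs <= 2 * my or nx <= 2 * mx:
        raise TrainingError(
            f"ACS {n_acs}x{nx} smaller than the receptive field "
            f"({2 * my + 1}x{2 * mx + 1}) of {network.method}"
        )
    if norm is None:
        _, norm = normalize_kspace(acs)
    acs_n = acs / norm.scale
    global_rows = mask.acs_start + np.arange(n_acs)
    on_lattice = (global_rows - mask.lattice_offset) % mask.R == 0
    inp = acs_n.copy()
    inp[:, ~on_lattice, :] = 0
    return TrainingPair(
        input=split_complex(inp),
        target=split_complex(acs_n),
        valid_rows=slice(my, n_acs - my),
        valid_cols=slice(mx, nx - mx),
        norm=norm,
    )


# ---------------------------------------------------------------------------
# numpy conv engine (im2col) with hand-derived gradients


def _im2col(x: np.ndarray, ky: int, kx: int) -> np.ndarray:
    """[C, H, W] -> [H*W, C*ky*kx] patches with zero 'same' padding."""
    C, H, W = x.shape
    py, px = ky // 2, kx // 2
    xp = np.pad(x, ((0, 0), (py, py), (px, px)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (ky, kx), axis=(1, 2))
    return np.ascontiguousarray(v.transpose(1, 2, 0, 3, 4)).reshape(H * W, C * ky * kx)


def _col2im(dpatches: np.ndarray, shape: tuple[int, int, int], ky: int, kx: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of patch gradients)."""
    C, H, W = shape
    py, px = ky // 2, kx // 2
    dxp = np.zeros((C, H + 2 * py, W + 2 * px))
    dp = dpatches.reshape(H, W, C, ky, kx)
    for i in range(ky):
        for j in range(kx):
            dxp[:, i : i + H, j : j + W] += dp[:, :, :, i, j].transpose(2, 0, 1)
    return dxp[:, py : py + H, px : px + W]


class _Conv:
    """Same-size 2D convolution layer with explicit forward/backward."""

    def __init__(self, spec: LayerSpec, W: np.ndarray, b: np.ndarray | None):
        self.spec = spec
        self.W = W  # [out, in, ky, kx]
        self.b = b

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.spec
        self._shape = x.shape
        self._patches = _im2col(x, s.kernel_ky, s.kernel_kx)
        y = self._patches @ self.W.reshape(s.out_channels, -1).T
        if self.b is not None:
            y = y + self.b
        H, W_ = x.shape[1], x.shape[2]
        y = y.T.reshape(s.out_channels, H, W_)
        if s.activation == "relu":
            self._pre = y
            y = np.maximum(y, 0.0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.spec
        if s.activation == "relu":
            dy = dy * (self._pre > 0)
        H, W_ = self._shape[1], self._shape[2]
        dym = dy.reshape(s.out_channels, H * W_).T  # [H*W, out]
        self.dW = (dym.T @ self._patches).reshape(self.W.shape)
        self.db = dy.sum(axis=(1, 2)) if self.b is not None else None
        dpatches = dym @ self.W.reshape(s.out_channels, -1)
        return _col2im(dpatches, self._shape, s.kernel_ky, s.kernel_kx)


def _init_layers(specs, rng) -> list[_Conv]:
    layers = []
    for s in specs:
        fan_in = s.in_channels * s.kernel_ky * s.kernel_kx
        scale = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-scale, scale, size=(s.out_channels, s.in_channels, s.kernel_ky, s.kernel_kx))
        b = np.zeros(s.out_channels) if s.has_bias else None
        layers.append(_Conv(s, W, b))
    return layers


def _forward_path(layers: list[_Conv], x: np.ndarray) -> np.ndarray:
    for l in layers:
        x = l.forward(x)
    return x


def _backward_path(layers: list[_Conv], dy: np.ndarray) -> None:
    for l in reversed(layers):
        dy = l.backward(dy)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (layer, attr) pairs
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, a)) for l, a in params]
        self.v = [np.zeros_like(getattr(l, a)) for l, a in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, ((layer, attr), g) in enumerate(zip(self.params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p = getattr(layer, attr)
            setattr(layer, attr, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class _Plateau:
    """Reduce-on-plateau schedule, relative-threshold semantics."""

    def __init__(self, optimizer, factor, patience, threshold):
        self.opt = optimizer
        self.factor, self.patience, self.threshold = factor, patience, threshold
        self.best = np.inf
        self.bad = 0

    def step(self, loss):
        if loss < self.best * (1.0 - self.threshold):
            self.best = loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr *= self.factor
                self.bad = 0


def _masked_mae_grad(pred, target, rows, cols):
    diff = pred - target
    region = diff[:, rows, cols]
    n = region.size
    loss = float(np.mean(np.abs(region)))
    grad = np.zeros_like(diff)
    grad[:, rows, cols] = np.sign(region) / n
    return loss, grad


def train_network(
    spec: NetworkSpec,
    pair: TrainingPair | list[TrainingPair],
    hyper: TrainingHyper | None = None,
    provenance: dict | None = None,
) -> WeightSet:
    """Train one network on one ACS pair (or jointly on several, averaging
    the loss) with full-batch Adam and the plateau schedule.

    The returned loss trace has ``epochs + 1`` entries: the loss evaluated
    before each update, plus the loss at the returned (final) weights. For
    rRAKI the recorded loss is MAE(sum-path, target) +
    ``lambda_combine`` * MAE(linear-path, target).
    """
    hyper = hyper or TrainingHyper()
    pairs = [pair] if isinstance(pair, TrainingPair) else list(pair)
    if not pairs:
        raise TrainingError("no training pairs supplied")
    for p in pairs:
        if p.input.shape[0] != 2 * spec.n_coils:
            raise ValueError("training pair channel count does not match the network")

    rng = np.random.default_rng(np.random.SeedSequence(hyper.seed))
    main = _init_layers(spec.layers, rng)
    lin = _init_layers(spec.linear_layers, rng)
    params = [(l, "W") for l in main + lin] + [
        (l, "b") for l in main + lin if l.b is not None
    ]
    opt = _Adam(params, hyper.lr)
    sched = _Plateau(opt, hyper.factor, hyper.patience, hyper.threshold)
    lam = hyper.lambda_combine

    def eval_loss_and_grads(do_backward: bool):
        total = 0.0
        grads = [np.zeros_like(getattr(l, a)) for l, a in params] if do_backward else None
        for p in pairs:
            y_main = _forward_path(main, p.input)
            if lin:
                y_lin = _forward_path(lin, p.input)
                y = y_main + y_lin
                l_sum, g_sum = _masked_mae_grad(y, p.target, p.valid_rows, p.valid_cols)
                l_lin, g_lin = _masked_mae_grad(y_lin, p.target, p.valid_rows, p.valid_cols)
                loss = l_sum + lam * l_lin
                if do_backward:
                    _backward_path(main, g_sum)
                    _backward_path(lin, g_sum + lam * g_lin)
            else:
                loss, g = _masked_mae_grad(y_main, p.target, p.valid_rows, p.valid_cols)
                if do_backward:
                    _backward_path(main, g)
            total += loss
            if do_backward:
                for i, (layer, attr) in enumerate(params):
                    grads[i] += getattr(layer, "d" + attr)
        total /= len(pairs)
        if do_backward:
            grads = [g / len(pairs) for g in grads]
        return total, grads

    trace = np.empty(hyper.epochs + 1)
    for epoch in range(hyper.epochs):
        loss, grads = eval_loss_and_grads(True)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        trace[epoch] = loss
        opt.step(grads)
        sched.step(loss)
    final_loss, _ = eval_loss_and_grads(False)
    if not np.isfinite(final_loss):
        raise DivergenceError(f"non-finite loss at epoch {hyper.epochs}")
    trace[-1] = final_loss

    return WeightSet(
        method=spec.method,
        spec=spec,
        layers=tuple((l.W.copy(), None if l.b is None else l.b.copy()) for l in main),
        linear_layers=tuple(
            (l.W.copy(), None if l.b is None else l.b.copy()) for l in lin
        ),
        norm=pairs[0].norm,
        provenance=dict(provenance or {}),
        loss_trace=trace,
    )


def _run_weights(weights: WeightSet, x: np.ndarray) -> np.ndarray:
    main = [_Conv(s, W, b) for s, (W, b) in zip(weights.spec.layers, weights.layers)]
    y = _forward_path(main, x)
    if weights.linear_layers:
        lin = [
            _Conv(s, W, b)
            for s, (W, b) in zip(weights.spec.linear_layers, weights.linear_layers)
        ]
        y = y + _forward_path(lin, x)
    return y


def apply_network(
    weights: WeightSet,
    zero_filled: np.ndarray,
    mask: SamplingMask,
    norm: NormalizationRecord | None = None,
) -> np.ndarray:
    """Predict the full k-space of a zero-filled frame and enforce data
    consistency with the measured rows."""
    zero_filled = np.asarray(zero_filled)
    if zero_filled.ndim != 3 or zero_filled.shape[0] != weights.spec.n_coils:
        raise ValueError(
            f"expected frame [{weights.spec.n_coils}, ny, nx], got {zero_filled.shape}"
        )
    norm = norm or weights.norm
    x = split_complex(zero_filled / norm.scale)
    pred = merge_complex(_run_weights(weights, x)) * norm.scale
    return data_consistency(pred, zero_filled, mask)


# ---------------------------------------------------------------------------
# estimator surface


class _ScanSpecificReconstructor(BaseEstimator):
    """Shared fit/transform machinery for the three scan-specific networks.

    ``fit(X, mask)`` trains on the ACS of the frame ``X`` (complex
    ``[n_coils, ny, nx]``); ``transform(X)`` fills the missing k-space
    lines; ``reconstruct(X)`` returns the SoS image.

    Attributes set by ``fit``: ``weights_``, ``loss_trace_``, ``mask_``,
    ``training_time_``.
    """

    _method: str = ""

    def __init__(
        self,
        epochs: int = 600,
        lr: float = 0.01,
        factor: float = 0.1,
        patience: int = 10,
        threshold: float = 1e-3,
        lambda_combine: float = 1.0,
        seed: int = 0,
    ):
        self.epochs = epochs
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.lambda_combine = lambda_combine
        self.seed = seed

    def _hyper(self) -> TrainingHyper:
        return TrainingHyper(
            epochs=self.epochs,
            lr=self.lr,
            factor=self.factor,
            patience=self.patience,
            threshold=self.threshold,
            lambda_combine=self.lambda_combine,
            seed=self.seed,
        )

    def fit(self, X, mask: SamplingMask):
        X = np.asarray(X)
        spec = build_network(self._method, X.shape[0])
        acs = extract_acs(undersample(X, mask), mask)
        pair = make_training_pair(acs, mask, spec)
        t0 = time.perf_counter()
        self.weights_ = train_network(spec, pair, self._hyper())
        self.training_time_ = time.perf_counter() - t0
        self.loss_trace_ = self.weights_.loss_trace
        self.mask_ = mask
        return self

    def transform(self, X) -> np.ndarray:
        measured = undersample(np.asarray(X), self.mask_)
        return apply_network(self.weights_, measured, self.mask_)

    def reconstruct(self, X) -> np.ndarray:
        return sos_combine(ifft2c(self.transform(X)))


class SrakiReconstructor(_ScanSpecificReconstructor):
    """Single linear 5x5 convolution trained on the ACS (simplified RAKI)."""

    _method = "sraki"


class RakiReconstructor(_ScanSpecificReconstructor):
    """Three-layer ReLU network trained on the ACS."""

    _method = "raki"


class RrakiReconstructor(_ScanSpecificReconstructor):
    """RAKI plus a parallel linear path, combined loss (residual RAKI)."""

    _method = "rraki"
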