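"""GRAPPA: least-squares calibration of a linear k-space interpolation kernel
on the ACS, then completion of the missing phase-encode lines.

Kernel geometry: ``n_source_lines`` acquired ky lines spaced ``R`` apart
(5 by default) by ``kx_taps`` readout taps (5 by default), over all coils.
For each missing-line offset ``d in {1, ..., R-1}`` a separate weight matrix
maps the flattened source neighborhood to all target coils; the target line
sits ``d`` rows below the middle source line. Calibration slides this
geometry across the ACS and solves the resulting least-squares system
(optionally Tikhonov-stabilized); application gathers the same geometry on
the zero-filled grid with zero-padding outside k-space.

Each target sample is accumulated with a single ``np.dot`` per (pixel, coil)
so that the reduction order is fixed and reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .sampling import SamplingMask, extract_acs, undersample
from .transforms import data_consistency, ifft2c, sos_combine

__all__ = [
    "GrappaKernelSpec",
    "GrappaWeights",
    "CalibrationError",
    "grappa_calibrate",
    "grappa_apply",
    "grappa_reconstruct",
    "GrappaReconstructor",
]

DEFAULT_RIDGE = 1e-6  # relative Tikhonov factor, scaled by trace(A^H A)/n_unknowns


class CalibrationError(ValueError):
    """ACS too small (or degenerate) to calibrate the requested kernel."""


@dataclass(frozen=True)
class GrappaKernelSpec:
    R: int
    n_source_lines: int = 5
    kx_taps: int = 5

    def __post_init__(self):
        if self.R < 1:
            raise ValueError(f"R must be >= 1, got {self.R}")
        if self.n_source_lines < 2:
            raise ValueError("n_source_lines must be >= 2")
        if self.kx_taps % 2 != 1:
            raise ValueError("kx_taps must be odd")

    @property
    def center_source(self) -> int:
        return self.n_source_lines // 2

    def n_unknowns(self, n_coils: int) -> int:
        return n_coils * self.n_source_lines * self.kx_taps


@dataclass(frozen=True)
class GrappaWeights:
    """One complex weight matrix ``[n_unknowns, n_coils]`` per missing offset."""

    spec: GrappaKernelSpec
    n_coils: int
    weights: dict  # offset d -> complex [K, n_coils]
    provenance: dict = field(default_factory=dict)


def _source_feature_block(frame: np.ndarray, rows: np.ndarray, kx_taps: int) -> np.ndarray:
    """Gather the source neighborhood for every readout position.

    ``frame``: complex [n_coils, ny, nx]; ``rows``: the n_src source row
    indices (entries outside [0, ny) contribute zeros). Returns
    ``[nx, n_coils * n_src * kx_taps]`` with feature order
    (coil-major, then source line, then kx tap).
    """
    nc, ny, nx = frame.shape
    px = kx_taps // 2
    src = np.zeros((len(rows), nc, nx + 2 * px), dtype=frame.dtype)
    for j, r in enumerate(rows):
        if 0 <= r < ny:
            src[j, :, px : px + nx] = frame[:, r, :]
    # [n_src, nc, nx, kx_taps] -> [nx, nc, n_src, kx_taps]
    win = np.lib.stride_tricks.sliding_window_view(src, kx_taps, axis=2)
    feats = np.ascontiguousarray(win.transpose(2, 1, 0, 3))
    return feats.reshape(nx, -1)


def grappa_calibrate(
    acs, spec: GrappaKernelSpec, ridge: float = DEFAULT_RIDGE
) -> GrappaWeights:
    """Fit the interpolation kernel to ACS data by (regularized) least squares.

    ``acs`` is a complex block ``[n_coils, n_acs, nx]`` or a sequence of such
    blocks whose calibration equations are stacked (shared calibration).
    ``ridge`` is a relative Tikhonov factor: the effective penalty is
    ``ridge * trace(A^H A) / n_unknowns``; ``ridge=0`` requests the plain
    minimum-norm least-squares solution.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    blocks = [np.asarray(acs)] if isinstance(acs, np.ndarray) else [np.asarray(a) for a in acs]
    if any(b.ndim != 3 for b in blocks):
        raise ValueError("each ACS block must be [n_coils, n_acs, nx]")
    nc = blocks[0].shape[0]
    if any(b.shape[0] != nc for b in blocks):
        raise ValueError("all ACS blocks must share the coil count")

    R, n_src, kx = spec.R, spec.n_source_lines, spec.kx_taps
    c_src = spec.center_source
    px = kx // 2
    K = spec.n_unknowns(nc)

    weights = {}
    for d in range(1, R) if R > 1 else []:
        A_rows, B_rows = [], []
        for block in blocks:
            _, n_acs, nx = block.shape
            for y0 in range(n_acs):
                src_rows = y0 + np.arange(n_src) * R
                ty = y0 + c_src * R + d
                if src_rows[-1] >= n_acs or ty >= n_acs:
                    break
                feats = _source_feature_block(block, src_rows, kx)
                A_rows.append(feats[px : nx - px])
                B_rows.append(block[:, ty, px : nx - px].T)
        if not A_rows:
            raise CalibrationError(
                f"ACS too small for kernel (offset {d}): need "
                f">= {(n_src - 1) * R + 1} rows and > {2 * px} readout columns"
            )
        A = np.concatenate(A_rows, axis=0)
        B = np.concatenate(B_rows, axis=0)
        if A.shape[0] == 0:
            raise CalibrationError(
                f"ACS readout extent too small for {kx} kx taps"
            )
        if not np.any(A):
            raise CalibrationError("all-zero ACS: calibration system is singular")
        if ridge == 0.0:
            w, *_ = np.linalg.lstsq(A, B, rcond=None)
        else:
            AhA = A.conj().T @ A
            lam = ridge * float(np.trace(AhA).real) / K
            w = np.linalg.solve(AhA + lam * np.eye(K), A.conj().T @ B)
        weights[d] = w
    return GrappaWeights(spec=spec, n_coils=nc, weights=weights)


def grappa_apply(
    weights: GrappaWeights, zero_filled: np.ndarray, mask: SamplingMask
) -> np.ndarray:
    """Interpolate every missing line of a zero-filled frame.

    Acquired rows are untouched; boundary source rows/columns outside
    k-space contribute zeros. Each target value is a single dot product of
    the gathered source vector with the offset's weight column.
    """
    zero_filled = np.asarray(zero_filled)
    if zero_filled.ndim != 3:
        raise ValueError("expected a frame [n_coils, ny, nx]")
    nc, ny, nx = zero_filled.shape
    if nc != weights.n_coils:
        raise ValueError(f"coil count {nc} != calibrated {weights.n_coils}")
    if mask.R != weights.spec.R:
        raise ValueError(f"mask R={mask.R} incompatible with weights R={weights.spec.R}")
    spec = weights.spec
    if spec.R == 1:
        return zero_filled.copy()

    out = zero_filled.copy()
    offsets = np.arange(spec.n_source_lines) - spec.center_source
    for r in np.flatnonzero(~mask.acquired):
        d = (r - mask.lattice_offset) % spec.R
        if d == 0:
            continue  # lattice rows are acquired by construction
        w = weights.weights[d]
        src_rows = (r - d) + offsets * spec.R
        feats = _source_feature_block(zero_filled, src_rows, spec.kx_taps)
        row = np.empty((nc, nx), dtype=complex)
        for x in range(nx):
            for c in range(nc):
                row[c, x] = np.dot(feats[x], w[:, c])
        out[:, r, :] = row
    return out


def grappa_reconstruct(
    frame: np.ndarray,
    mask: SamplingMask,
    spec: GrappaKernelSpec | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> np.ndarray:
    """Calibrate on the frame's ACS, fill k-space, and return the SoS image."""
    rec = GrappaReconstructor(
        n_source_lines=(spec.n_source_lines if spec else 5),
        kx_taps=(spec.kx_taps if spec else 5),
        ridge=ridge,
    )
    return rec.fit(frame, mask).reconstruct(frame)


class GrappaReconstructor(BaseEstimator):
    """Scikit-learn style GRAPPA estimator.

    ``fit(X, mask)`` extracts the ACS from the frame ``X`` (complex
    ``[n_coils, ny, nx]``) and calibrates the kernel; ``transform(X)``
    returns the completed k-space with data consistency enforced;
    ``reconstruct(X)`` additionally applies the inverse FFT and SoS coil
    combination.

    Attributes set by ``fit``: ``weights_`` (:class:`GrappaWeights`),
    ``mask_``, ``calibration_time_``.
    """

    def __init__(self, n_source_lines: int = 5, kx_taps: int = 5, ridge: float = DEFAULT_RIDGE):
        self.n_source_lines = n_source_lines
        self.kx_taps = kx_taps
        self.ridge = ridge

    def fit(self, X, mask: SamplingMask):
        X = np.asarray(X)
        spec = GrappaKernelSpec(
            R=mask.R, n_source_lines=self.n_source_lines, kx_taps=self.kx_taps
        )
        acs = extract_acs(undersample(X, mask), mask)
        t0 = time.perf_counter()
        self.weights_ = grappa_calibrate(acs, spec, ridge=self.ridge)
        self.calibration_time_ = time.perf_counter() - t0
        self.mask_ = mask
        return self

    def transform(self, X) -> np.ndarray:
        measured = undersample(np.asarray(X), self.mask_)
        filled = grappa_apply(self.weights_, measured, self.mask_)
        return data_consistency(filled, measured, self.mask_)

    def reconstruct(self, X) -> np.ndarray:
        return sos_combine(ifft2c(self.transform(X)))
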