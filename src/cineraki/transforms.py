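"""Centered unitary Fourier transforms, coil combination, and k-space utilities.

Conventions used everywhere in this package:

* k-space frames are complex arrays ``[..., n_coils, ny, nx]`` with the DC
  sample at index ``(ny // 2, nx // 2)``;
* Fourier transforms are unitary (``norm="ortho"``), so Parseval holds
  exactly and image/k-space energies agree;
* real "channel stacks" pack a complex multi-coil array as
  ``[Re(c0) ... Re(cN-1), Im(c0) ... Im(cN-1)]`` along the coil axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "sos_combine",
    "split_complex",
    "merge_complex",
    "data_consistency",
    "normalize_kspace",
    "denormalize_kspace",
    "NormalizationRecord",
]

_AXES = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered, unitary 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Centered, unitary inverse 2D FFT over the last two axes.

    Inverse of :func:`fft2c`; a unit impulse at the DC bin maps to the
    constant image ``1 / sqrt(ny * nx)``.
    """
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def sos_combine(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares coil combination.

    Parameters
    ----------
    coil_images : complex array ``[..., n_coils, ny, nx]``

    Returns
    -------
    real array ``[..., ny, nx]``, nonnegative.
    """
    coil_images = np.asarray(coil_images)
    if coil_images.ndim < 3:
        raise ValueError("coil_images must have shape [..., n_coils, ny, nx]")
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=-3))


def split_complex(k: np.ndarray) -> np.ndarray:
    """Pack a complex ``[n_coils, ny, nx]`` array as real ``[2*n_coils, ny, nx]``.

    Channel order is real parts of all coils, then imaginary parts.
    """
    k = np.asarray(k)
    if k.ndim != 3:
        raise ValueError("expected a single frame [n_coils, ny, nx]")
    return np.concatenate([k.real, k.imag], axis=0)


def merge_complex(c: np.ndarray) -> np.ndarray:
    """Inverse of :func:`split_complex` (bit-exact round trip)."""
    c = np.asarray(c)
    if c.ndim != 3 or c.shape[0] % 2 != 0:
        raise ValueError("channel stack must have an even channel count")
    n = c.shape[0] // 2
    return c[:n] + 1j * c[n:]


def data_consistency(
    predicted: np.ndarray, measured: np.ndarray, mask
) -> np.ndarray:
    """Replace predicted k-space rows with measured values where acquired.

    ``mask`` is a :class:`~cineraki.sampling.SamplingMask` (or any object with
    a boolean ``acquired`` attribute over the phase-encode axis). Acquired
    rows are copied from ``measured`` bit-exactly; missing rows keep the
    predicted values. Idempotent.
    """
    predicted = np.asarray(predicted)
    measured = np.asarray(measured)
    if predicted.shape != measured.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs measured {measured.shape}"
        )
    acquired = np.asarray(mask.acquired, dtype=bool)
    if acquired.shape[0] != predicted.shape[-2]:
        raise ValueError("mask length does not match the phase-encode size")
    out = predicted.copy()
    out[..., acquired, :] = measured[..., acquired, :]
    return out


@dataclass(frozen=True)
class NormalizationRecord:
    """Scale applied to k-space before training/inference (``scale > 0``)."""

    scale: float

    def __post_init__(self):
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"normalization scale must be positive, got {self.scale}")


def normalize_kspace(
    k: np.ndarray, rows: slice | None = None
) -> tuple[np.ndarray, NormalizationRecord]:
    """Scale k-space so the largest magnitude (over ``rows``, e.g. the ACS)
    equals 1.

    Returns the scaled array and a :class:`NormalizationRecord` holding the
    recorded scale (the maximum magnitude found). Raises on all-zero input.
    """
    k = np.asarray(k)
    region = k if rows is None else k[..., rows, :]
    scale = float(np.max(np.abs(region)))
    if scale == 0.0:
        raise ValueError("cannot normalize all-zero k-space")
    return k / scale, NormalizationRecord(scale=scale)


def denormalize_kspace(k: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    """Undo :func:`normalize_kspace` (identity within 1e-12)."""
    return np.asarray(k) * record.scale
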