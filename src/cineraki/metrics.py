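"""Reference-based image quality metrics on the heart ROI: PSNR, NMSE, SSIM.

PSNR = 10 log10(MAX_I^2 / MSE) with MAX_I the maximum reference pixel over
the ROI; NMSE = MSE / mean(I^2); SSIM is the canonical three-component form
(luminance, contrast, structure) with c3 = c2/2, evaluated on 7x7 uniform
windows fully contained in the ROI after normalizing both images by MAX_I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import ROI

__all__ = ["SSIMParams", "MetricsReport", "psnr", "nmse", "ssim", "evaluate_stack"]


@dataclass(frozen=True)
class SSIMParams:
    data_range: float = 1.0
    window: int = 7
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


def _crop(ref, est, roi: ROI | None):
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {est.shape}")
    if roi is not None:
        ref = ref[roi.rows, roi.cols]
        est = est[roi.rows, roi.cols]
    return ref, est


def psnr(reference, estimate, roi: ROI | None = None) -> float:
    """Peak signal-to-noise ratio in dB over the ROI; ``inf`` if MSE is 0."""
    ref, est = _crop(reference, estimate, roi)
    if not np.any(ref):
        raise ValueError("reference is identically zero on the ROI")
    mse = float(np.mean((ref - est) ** 2))
    if mse == 0.0:
        return np.inf
    max_i = float(np.max(ref))
    return 10.0 * np.log10(max_i**2 / mse)


def nmse(reference, estimate, roi: ROI | None = None) -> float:
    """Mean squared error normalized by the reference power over the ROI."""
    ref, est = _crop(reference, estimate, roi)
    power = float(np.mean(ref**2))
    if power == 0.0:
        raise ValueError("reference is identically zero on the ROI")
    return float(np.mean((ref - est) ** 2)) / power


def ssim(reference, estimate, roi: ROI | None = None, params: SSIMParams | None = None) -> float:
    """Mean windowed structural similarity over the ROI.

    Both images are divided by the reference ROI maximum first, so the
    stabilization constants refer to a data range of 1. Windows are uniform
    ``window x window`` patches fully inside the ROI; moments use the
    population convention.
    """
    params = params or SSIMParams()
    ref, est = _crop(reference, estimate, roi)
    w = params.window
    if ref.shape[0] < w or ref.shape[1] < w:
        raise ValueError(f"ROI {ref.shape} smaller than the {w}x{w} SSIM window")
    max_i = float(np.max(np.abs(ref)))
    if max_i == 0.0:
        raise ValueError("reference is identically zero on the ROI")
    x = ref / max_i
    y = est / max_i

    def windows(img):
        return np.lib.stride_tricks.sliding_window_view(img, (w, w))

    wx, wy = windows(x), windows(y)
    mu_x = wx.mean(axis=(-2, -1))
    mu_y = wy.mean(axis=(-2, -1))
    var_x = (wx**2).mean(axis=(-2, -1)) - mu_x**2
    var_y = (wy**2).mean(axis=(-2, -1)) - mu_y**2
    cov = (wx * wy).mean(axis=(-2, -1)) - mu_x * mu_y
    sx = np.sqrt(np.maximum(var_x, 0.0))
    sy = np.sqrt(np.maximum(var_y, 0.0))
    c1, c2, c3 = params.c1, params.c2, params.c3
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    con = (2 * sx * sy + c2) / (var_x + var_y + c2)
    struct = (cov + c3) / (sx * sy + c3)
    return float(np.mean(lum * con * struct))


@dataclass
class MetricsReport:
    """Per-frame PSNR/SSIM/NMSE plus mean +/- std aggregates."""

    psnr: np.ndarray  # [n_slices, n_phases]
    ssim: np.ndarray
    nmse: np.ndarray
    roi: ROI | None = None

    @property
    def n_frames(self) -> int:
        return self.psnr.size

    def summary(self) -> dict:
        out = {}
        for name in ("psnr", "ssim", "nmse"):
            v = getattr(self, name).ravel()
            with np.errstate(invalid="ignore"):
                std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            out[name] = (float(np.mean(v)), std)
        return out

    def to_tsv(self) -> str:
        lines = ["slice\tphase\tpsnr\tssim\tnmse"]
        S, P = self.psnr.shape
        for s in range(S):
            for p in range(P):
                lines.append(
                    f"{s}\t{p}\t{self.psnr[s, p]:.6g}\t{self.ssim[s, p]:.6g}\t{self.nmse[s, p]:.6g}"
                )
        lines.append("")
        for name, (m, sd) in self.summary().items():
            lines.append(f"# {name}: {m:.6g} +/- {sd:.6g}")
        return "\n".join(lines) + "\n"


def evaluate_stack(recon, truth) -> MetricsReport:
    """Per-frame metrics of a reconstruction against the phantom truth.

    ``recon`` is a ``ReconResult`` or a real array ``[S, P, ny, nx]``;
    ``truth`` a ``CineTruth``. Metrics are evaluated on the heart ROI.
    """
    images = getattr(recon, "images", recon)
    images = np.asarray(images)
    ref = truth.sos_images
    if images.shape != ref.shape:
        raise ValueError(f"shape mismatch: recon {images.shape} vs truth {ref.shape}")
    roi = truth.heart_roi
    S, P = ref.shape[:2]
    rep = MetricsReport(
        psnr=np.empty((S, P)), ssim=np.empty((S, P)), nmse=np.empty((S, P)), roi=roi
    )
    for s in range(S):
        for p in range(P):
            rep.psnr[s, p] = psnr(ref[s, p], images[s, p], roi)
            rep.ssim[s, p] = ssim(ref[s, p], images[s, p], roi)
            rep.nmse[s, p] = nmse(ref[s, p], images[s, p], roi)
    return rep
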