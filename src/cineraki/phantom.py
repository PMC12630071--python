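"""Synthetic multi-slice, multi-phase, multi-coil cine k-space with known truth.

The phantom emulates a short-axis cine stack at desk scale: a static "body"
(superposed smooth-edged ellipses: torso, lungs, spine analog), a "heart"
disc whose radius breathes periodically over the cardiac cycle, smooth
complex coil-sensitivity profiles arranged on a ring around the field of
view, and additive complex Gaussian noise injected in k-space after full
sampling (matching where acquisition noise actually enters).

Two statistical features drive everything downstream and are built in by
construction:

* **phase stability** — coil profiles are identical for every cardiac phase
  of a slice, so linear interpolation weights are (near) phase-invariant;
* **slice drift** — the coil-center ring rotates and the anatomy rescales
  smoothly with slice index, so weights decorrelate with slice distance at a
  rate set by ``slice_drift``.

All randomness flows from a single seed through named sub-streams, so every
array is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .transforms import fft2c, ifft2c, sos_combine

__all__ = [
    "PhantomConfig",
    "CoilProfileSet",
    "CineTruth",
    "ROI",
    "make_coil_sensitivities",
    "generate_cine_truth",
    "heart_roi",
]

ROI_SIZE = 70  # nominal heart-ROI side length, pixels
_EDGE = 1.5  # smoothstep edge width, pixels


def _stream(seed: int, *keys) -> np.random.Generator:
    """Named random sub-stream: one generator per (seed, purpose, index...)."""
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=ints))


@dataclass(frozen=True)
class ROI:
    """Half-open pixel rectangle ``[row_start, row_stop) x [col_start, col_stop)``."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    @property
    def rows(self) -> slice:
        return slice(self.row_start, self.row_stop)

    @property
    def cols(self) -> slice:
        return slice(self.col_start, self.col_stop)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, motion, drift and noise parameters of the cine phantom.

    Defaults are a scaled-down short-axis stack: 9 slices, 8 cardiac phases,
    8 coils on a 96x96 matrix, mild inter-slice drift and a small k-space
    noise floor (std relative to the DC-normalized k-space magnitude).
    """

    ny: int = 96
    nx: int = 96
    n_slices: int = 9
    n_phases: int = 8
    n_coils: int = 8
    heart_center: tuple[int, int] | None = None
    heart_radius_range: tuple[float, float] = (9.0, 15.0)
    slice_drift: float = 0.15
    noise_std: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.ny < 32 or self.nx < 32:
            raise ValueError("ny and nx must be >= 32")
        if self.n_coils < 1 or self.n_slices < 1 or self.n_phases < 1:
            raise ValueError("n_slices, n_phases, n_coils must be >= 1")
        if self.heart_radius_range[0] > self.heart_radius_range[1]:
            raise ValueError("heart_radius_range must be (min, max) with min <= max")
        if self.slice_drift < 0 or self.noise_std < 0:
            raise ValueError("slice_drift and noise_std must be >= 0")
        center = self.center
        if not (0 <= center[0] < self.ny and 0 <= center[1] < self.nx):
            raise ValueError(f"heart_center {center} outside the image grid")

    @property
    def center(self) -> tuple[int, int]:
        if self.heart_center is None:
            return (self.ny // 2, self.nx // 2)
        return self.heart_center


@dataclass(frozen=True)
class CoilProfileSet:
    """Smooth complex sensitivity maps ``[n_coils, ny, nx]`` for one slice."""

    profiles: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.profiles.shape[0]


@dataclass(frozen=True)
class CineTruth:
    """Fully sampled phantom stack with its noise-free image-domain truth."""

    kspace: np.ndarray  # complex [slice, phase, coil, ky, kx]
    coil_images: np.ndarray  # complex [slice, phase, coil, ny, nx], noise-free
    sos_images: np.ndarray  # real [slice, phase, ny, nx]
    heart_roi: ROI
    config: PhantomConfig

    @property
    def shape(self) -> tuple[int, ...]:
        return self.kspace.shape


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _soft_ellipse(yy, xx, cy, cx, ry, rx, width=_EDGE):
    """Smooth-edged ellipse indicator; support strictly inside the ellipse."""
    rho = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    # normalized edge width ~ width pixels at the boundary of the minor axis
    w = width / min(ry, rx)
    return _smoothstep((1.0 - rho) / w)


def make_coil_sensitivities(
    n_coils: int,
    ny: int,
    nx: int,
    slice_index: int = 0,
    slice_drift: float = 0.0,
    bandlimit: int | None = None,
    seed: int = 0,
    uniform: bool = False,
) -> CoilProfileSet:
    """Smooth complex coil sensitivities for one slice.

    Coil centers sit on a ring enclosing the FOV; the ring is rotated by
    ``slice_drift * slice_index`` radians, which is the sole source of
    slice-to-slice sensitivity change (callers pass a signed slice offset
    from the stack middle). Per-coil Gaussian magnitude falloff is modulated
    by a smooth seeded complex phase ramp that does not depend on the slice.

    With ``bandlimit=b`` (odd), profiles are synthesized from only the
    central ``b x b`` block of their centered 2D spectrum, so the spectrum
    outside that block is zero (to numerical precision). ``uniform=True``
    returns identically-1 profiles.
    """
    if n_coils < 1 or ny <= 0 or nx <= 0:
        raise ValueError("n_coils, ny, nx must be positive")
    if bandlimit is not None:
        if bandlimit % 2 != 1 or bandlimit < 1 or bandlimit > min(ny, nx):
            raise ValueError("bandlimit must be an odd integer <= min(ny, nx)")
    if uniform:
        return CoilProfileSet(np.ones((n_coils, ny, nx), dtype=complex))

    rng = _stream(seed, "coilphase")
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    ring_r = 0.55 * max(ny, nx)
    sigma = 0.30 * max(ny, nx)
    profiles = np.empty((n_coils, ny, nx), dtype=complex)
    # phase-ramp coefficients: seeded once, independent of slice
    ramps = rng.uniform(-1.0, 1.0, size=(n_coils, 3))
    for c in range(n_coils):
        theta = 2.0 * np.pi * c / n_coils + slice_drift * slice_index
        ccy = cy0 + ring_r * np.sin(theta)
        ccx = cx0 + ring_r * np.cos(theta)
        d2 = (yy - ccy) ** 2 + (xx - ccx) ** 2
        mag = np.exp(-d2 / (2.0 * sigma**2))
        phase = (
            2.0 * np.pi * (ramps[c, 0] * (yy - cy0) / ny + ramps[c, 1] * (xx - cx0) / nx) * 0.35
            + np.pi * ramps[c, 2]
        )
        profiles[c] = mag * np.exp(1j * phase)
    if bandlimit is not None:
        b = bandlimit
        spec = fft2c(profiles)
        r0, c0 = ny // 2 - b // 2, nx // 2 - b // 2
        core = np.zeros_like(spec)
        core[:, r0 : r0 + b, c0 : c0 + b] = spec[:, r0 : r0 + b, c0 : c0 + b]
        profiles = ifft2c(core)
    return CoilProfileSet(profiles=profiles)


def heart_roi(config: PhantomConfig) -> ROI:
    """The nominal 70x70 metric ROI centered on the heart, clipped to bounds.

    The ideal interval ``[center - 35, center + 35)`` is intersected with the
    image; the result may be smaller than 70 on a side near an edge.
    """
    cy, cx = config.center
    half = ROI_SIZE // 2
    r0, r1 = max(0, cy - half), min(config.ny, cy - half + ROI_SIZE)
    c0, c1 = max(0, cx - half), min(config.nx, cx - half + ROI_SIZE)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("heart ROI does not intersect the image")
    return ROI(r0, r1, c0, c1)


def heart_radius(config: PhantomConfig, phase: int) -> float:
    """Heart radius at a cardiac phase: one full smooth cycle over n_phases."""
    r_min, r_max = config.heart_radius_range
    return r_min + (r_max - r_min) * (1.0 - np.cos(2.0 * np.pi * phase / config.n_phases)) / 2.0


def _body_image(config: PhantomConfig, slice_offset: float) -> np.ndarray:
    """Static (phase-independent) anatomy for one slice."""
    ny, nx = config.ny, config.nx
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    scale = float(np.clip(1.0 - 0.04 * config.slice_drift * slice_offset, 0.7, 1.3))
    img = np.zeros((ny, nx))
    # torso
    img += 1.0 * _soft_ellipse(yy, xx, cy0, cx0, 0.40 * ny * scale, 0.46 * nx * scale)
    # lungs (darker)
    img -= 0.45 * _soft_ellipse(yy, xx, cy0 - 0.08 * ny, cx0 - 0.22 * nx, 0.16 * ny * scale, 0.12 * nx * scale)
    img -= 0.45 * _soft_ellipse(yy, xx, cy0 - 0.08 * ny, cx0 + 0.22 * nx, 0.16 * ny * scale, 0.12 * nx * scale)
    # spine analog (brighter)
    img += 0.55 * _soft_ellipse(yy, xx, cy0 + 0.30 * ny, cx0, 0.07 * ny, 0.06 * nx)
    # fixed small ellipses (vessel/trabecula analogs): static across phases,
    # seeded once, drifting with the slice like the rest of the anatomy
    rng = _stream(config.seed, "texture")
    for _ in range(12):
        dy = rng.uniform(-0.30, 0.30) * ny * scale
        dx = rng.uniform(-0.36, 0.36) * nx * scale
        ry = rng.uniform(1.5, 4.0)
        rx = rng.uniform(1.5, 4.0)
        amp = rng.uniform(0.15, 0.3) * rng.choice([-1.0, 1.0])
        img += amp * _soft_ellipse(yy, xx, cy0 + dy, cx0 + dx, ry, rx, width=1.0)
    return img


def generate_cine_truth(config: PhantomConfig) -> CineTruth:
    """Generate the fully sampled phantom stack.

    The heart disc is the only phase-dependent structure, so any two phases
    of a slice differ only inside a disc of the maximal heart radius around
    ``heart_center``. Noise (if any) is added to k-space only; the stored
    ``coil_images``/``sos_images`` remain the noise-free ground truth.
    """
    roi = heart_roi(config)
    ny, nx = config.ny, config.nx
    S, P, C = config.n_slices, config.n_phases, config.n_coils
    mid = (S - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    cy, cx = config.center

    coil_images = np.empty((S, P, C, ny, nx), dtype=complex)
    for s in range(S):
        off = s - mid
        body = _body_image(config, off)
        prof = make_coil_sensitivities(
            C, ny, nx, slice_index=off, slice_drift=config.slice_drift, seed=config.seed
        ).profiles
        for p in range(P):
            r = heart_radius(config, p)
            rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            heart = 0.8 * _smoothstep((r - rr) / _EDGE)
            img = body + heart
            coil_images[s, p] = prof * img

    kspace = fft2c(coil_images)
    if config.noise_std > 0:
        ref = float(np.max(np.abs(kspace)))
        for s in range(S):
            g = _stream(config.seed, "noise", s)
            noise = g.standard_normal((P, C, ny, nx)) + 1j * g.standard_normal((P, C, ny, nx))
            kspace[s] += config.noise_std * ref * noise / np.sqrt(2.0)

    sos = sos_combine(coil_images)
    return CineTruth(
        kspace=kspace, coil_images=coil_images, sos_images=sos, heart_roi=roi, config=config
    )
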