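"""Uniform retrospective undersampling with a centered ACS block.

A scheme is uniform acceleration ``R`` (keep one of every ``R`` phase-encode
lines, lattice anchored at row 0) plus ``n_acs`` contiguous fully sampled
auto-calibration lines centered at ``ny // 2``. The acquired set is the union
of both; indices are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SamplingScheme", "SamplingMask", "build_mask", "undersample", "extract_acs"]

# R / ACS pairings used for the cine evaluations
PRESETS = {4: 26, 5: 30, 6: 36}


@dataclass(frozen=True)
class SamplingScheme:
    R: int
    n_acs: int
    ny: int

    def __post_init__(self):
        if self.R < 1:
            raise ValueError(f"acceleration rate must be >= 1, got {self.R}")
        if not (1 <= self.n_acs <= self.ny):
            raise ValueError(
                f"n_acs must be in [1, ny={self.ny}], got {self.n_acs}"
            )


@dataclass(frozen=True)
class SamplingMask:
    """Per-line acquisition pattern for one phase-encode axis."""

    acquired: np.ndarray  # bool [ny]
    acs_start: int
    acs_stop: int  # half-open
    R: int
    lattice_offset: int = 0

    @property
    def ny(self) -> int:
        return self.acquired.shape[0]

    @property
    def n_acs(self) -> int:
        return self.acs_stop - self.acs_start

    @property
    def acs_rows(self) -> slice:
        return slice(self.acs_start, self.acs_stop)

    def to_text(self) -> str:
        """One 0/1 character per row, one row per line."""
        return "\n".join("1" if a else "0" for a in self.acquired)


def build_mask(scheme: SamplingScheme) -> SamplingMask:
    """Build the acquisition mask for a :class:`SamplingScheme`.

    Acquired rows are the union of the lattice ``{r : r % R == 0}`` and the
    centered ACS interval ``[ny//2 - n_acs//2, ny//2 - n_acs//2 + n_acs)``.
    Pure function of the scheme.
    """
    R, n_acs, ny = scheme.R, scheme.n_acs, scheme.ny
    if R > 1 and n_acs + R > ny:
        raise ValueError(
            f"scheme (R={R}, n_acs={n_acs}, ny={ny}) leaves no non-ACS acquired line"
        )
    start = ny // 2 - n_acs // 2
    stop = start + n_acs
    acquired = np.zeros(ny, dtype=bool)
    acquired[::R] = True
    acquired[start:stop] = True
    return SamplingMask(acquired=acquired, acs_start=start, acs_stop=stop, R=R)


def undersample(kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Zero out non-acquired phase-encode rows (axis -2).

    Acquired rows are returned bit-identical to the input; idempotent.
    """
    kspace = np.asarray(kspace)
    if kspace.shape[-2] != mask.ny:
        raise ValueError(
            f"k-space ky size {kspace.shape[-2]} != mask length {mask.ny}"
        )
    out = kspace.copy()
    out[..., ~mask.acquired, :] = 0
    return out


def extract_acs(kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Return the contiguous ACS rows ``[..., n_acs, nx]``, untouched."""
    kspace = np.asarray(kspace)
    if kspace.shape[-2] != mask.ny:
        raise ValueError(
            f"k-space ky size {kspace.shape[-2]} != mask length {mask.ny}"
        )
    return kspace[..., mask.acs_rows, :].copy()
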