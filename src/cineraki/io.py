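"""HDF5 container for cine k-space, masks, truth, weights and results.

Layout (all complex data stored as paired real datasets for portability):

    /kspace/real, /kspace/imag   [slice, phase, coil, ky, kx]
    /mask/acquired               bool [ny] (+ R, n_acs, acs_start, ... attrs)
    /truth/sos                   [slice, phase, ny, nx] (+ ROI attrs)
    /recon/sos                   [slice, phase, ny, nx] (+ timing attrs)
    /weights/<name>/...          per-layer (or per-offset) datasets

Root attributes record the conventions (DC position, channel packing order,
container version) so any HDF5 consumer can interpret the data. An optional
read-only path accepts raw-acquisition files in the ISMRMRD HDF5 layout
(as distributed by the OCMR database) and reorders acquisitions into the
``[slice, phase, coil, ky, kx]`` convention.
"""

from __future__ import annotations

import os

import h5py
import numpy as np

from .grappa import GrappaKernelSpec, GrappaWeights
from .nets import WeightSet, build_network
from .phantom import ROI, CineTruth
from .sampling import SamplingMask
from .transforms import NormalizationRecord

__all__ = [
    "write_cine",
    "read_cine",
    "write_mask",
    "read_mask",
    "write_truth",
    "read_truth",
    "write_recon",
    "read_recon",
    "save_weight_set",
    "load_weight_set",
]

_CONVENTIONS = {
    "dc_position": "floor_n_over_2",
    "channel_order": "real_then_imag_coil_major",
    "container_version": "1",
}


def _open(path, mode):
    try:
        return h5py.File(path, mode)
    except OSError as e:
        raise OSError(f"cannot open container {path!r}: {e}") from e


def _tag(f: h5py.File) -> None:
    for k, v in _CONVENTIONS.items():
        f.attrs[k] = v


def write_cine(path: str, kspace: np.ndarray, mode: str = "a") -> None:
    """Write the complex stack ``[S, P, C, ky, kx]`` as paired real datasets."""
    kspace = np.asarray(kspace)
    with _open(path, mode) as f:
        _tag(f)
        if "kspace" in f:
            del f["kspace"]
        g = f.create_group("kspace")
        g.create_dataset("real", data=kspace.real)
        g.create_dataset("imag", data=kspace.imag)


def read_cine(path: str, dialect: str = "container"):
    """Read a cine stack; returns ``(kspace [S,P,C,ky,kx], meta dict)``.

    ``dialect="container"`` reads this package's layout; ``"ismrmrd"`` reads
    a raw ISMRMRD-style acquisition file (Cartesian, fully sampled).
    """
    if dialect == "container":
        if not os.path.exists(path):
            raise OSError(f"no such file: {path}")
        with _open(path, "r") as f:
            if "kspace" not in f:
                raise OSError(f"container {path!r} has no /kspace group")
            k = f["kspace/real"][()] + 1j * f["kspace/imag"][()]
            meta = dict(f.attrs)
        return k, meta
    if dialect == "ismrmrd":
        return _read_ismrmrd(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_ismrmrd(path: str):
    """Minimal reader for ISMRMRD-style raw files (OCMR layout).

    Expects ``/dataset/data`` as a compound dataset whose ``head`` field
    carries the slice/phase/line counters and whose ``data`` field holds
    interleaved float32 (re, im) samples per active channel. Acquisitions
    are reordered into ``[slice, phase, coil, ky, kx]`` with the phase-encode
    center shifted to ``ny // 2``.
    """
    if not os.path.exists(path):
        raise OSError(f"no such file: {path}")
    with _open(path, "r") as f:
        if "dataset" not in f or "data" not in f["dataset"]:
            raise OSError(f"{path!r} is not an ISMRMRD-style file (missing /dataset/data)")
        raw = f["dataset/data"][()]
    heads = raw["head"]
    idx = heads["idx"]
    slices = idx["slice"].astype(int)
    phases = idx["phase"].astype(int)
    lines = idx["kspace_encode_step_1"].astype(int)
    nchan = int(heads["active_channels"].max())
    nsamp = int(heads["number_of_samples"].max())
    S, P, ny = slices.max() + 1, phases.max() + 1, lines.max() + 1
    k = np.zeros((S, P, nchan, ny, nsamp), dtype=complex)
    for i in range(raw.shape[0]):
        d = np.asarray(raw["data"][i], dtype=np.float32).reshape(nchan, nsamp, 2)
        k[slices[i], phases[i], :, lines[i], :] = d[..., 0] + 1j * d[..., 1]
    # shift the acquired center line (max-energy line) to ny // 2
    energy = np.abs(k).sum(axis=(0, 1, 2, 4))
    shift = ny // 2 - int(np.argmax(energy))
    k = np.roll(k, shift, axis=3)
    meta = {"source": "ismrmrd", "center_shift": shift, **_CONVENTIONS}
    return k, meta


def write_mask(path: str, mask: SamplingMask, mode: str = "a") -> None:
    with _open(path, mode) as f:
        _tag(f)
        if "mask" in f:
            del f["mask"]
        g = f.create_group("mask")
        g.create_dataset("acquired", data=mask.acquired)
        g.attrs.update(
            R=mask.R,
            acs_start=mask.acs_start,
            acs_stop=mask.acs_stop,
            lattice_offset=mask.lattice_offset,
        )


def read_mask(path: str) -> SamplingMask:
    with _open(path, "r") as f:
        if "mask" not in f:
            raise OSError(f"container {path!r} has no /mask group")
        g = f["mask"]
        return SamplingMask(
            acquired=g["acquired"][()].astype(bool),
            acs_start=int(g.attrs["acs_start"]),
            acs_stop=int(g.attrs["acs_stop"]),
            R=int(g.attrs["R"]),
            lattice_offset=int(g.attrs["lattice_offset"]),
        )


def write_truth(path: str, truth: CineTruth, mode: str = "a") -> None:
    """Store the ground-truth SoS images and the heart ROI."""
    with _open(path, mode) as f:
        _tag(f)
        if "truth" in f:
            del f["truth"]
        g = f.create_group("truth")
        g.create_dataset("sos", data=truth.sos_images)
        r = truth.heart_roi
        g.attrs.update(
            roi_row_start=r.row_start,
            roi_row_stop=r.row_stop,
            roi_col_start=r.col_start,
            roi_col_stop=r.col_stop,
        )


def read_truth(path: str):
    """Returns ``(sos_images, ROI)``."""
    with _open(path, "r") as f:
        if "truth" not in f:
            raise OSError(f"container {path!r} has no /truth group")
        g = f["truth"]
        roi = ROI(
            int(g.attrs["roi_row_start"]),
            int(g.attrs["roi_row_stop"]),
            int(g.attrs["roi_col_start"]),
            int(g.attrs["roi_col_stop"]),
        )
        return g["sos"][()], roi


def write_recon(path: str, images: np.ndarray, timing: dict | None = None, mode: str = "a") -> None:
    with _open(path, mode) as f:
        _tag(f)
        if "recon" in f:
            del f["recon"]
        g = f.create_group("recon")
        g.create_dataset("sos", data=np.asarray(images))
        for k, v in (timing or {}).items():
            g.attrs[k] = v


def read_recon(path: str):
    with _open(path, "r") as f:
        if "recon" not in f:
            raise OSError(f"container {path!r} has no /recon group")
        g = f["recon"]
        return g["sos"][()], dict(g.attrs)


def save_weight_set(path: str, name: str, ws: WeightSet | GrappaWeights, mode: str = "a") -> None:
    """Serialize one trained weight set under ``/weights/<name>``."""
    with _open(path, mode) as f:
        _tag(f)
        root = f.require_group("weights")
        if name in root:
            del root[name]
        g = root.create_group(name)
        if isinstance(ws, GrappaWeights):
            g.attrs.update(
                method="grappa",
                R=ws.spec.R,
                n_source_lines=ws.spec.n_source_lines,
                kx_taps=ws.spec.kx_taps,
                n_coils=ws.n_coils,
            )
            for d, w in ws.weights.items():
                g.create_dataset(f"offset{d}_real", data=w.real)
                g.create_dataset(f"offset{d}_imag", data=w.imag)
        else:
            g.attrs.update(method=ws.method, n_coils=ws.spec.n_coils, scale=ws.norm.scale)
            for key, val in ws.provenance.items():
                g.attrs[f"prov_{key}"] = str(val)
            for prefix, layers in (("layer", ws.layers), ("linear", ws.linear_layers)):
                for i, (W, b) in enumerate(layers):
                    g.create_dataset(f"{prefix}{i}_W", data=W)
                    if b is not None:
                        g.create_dataset(f"{prefix}{i}_b", data=b)
            if ws.loss_trace is not None:
                g.create_dataset("loss_trace", data=ws.loss_trace)


def load_weight_set(path: str, name: str):
    """Inverse of :func:`save_weight_set` (provenance restored as strings)."""
    with _open(path, "r") as f:
        g = f[f"weights/{name}"]
        method = g.attrs["method"]
        if method == "grappa":
            spec = GrappaKernelSpec(
                R=int(g.attrs["R"]),
                n_source_lines=int(g.attrs["n_source_lines"]),
                kx_taps=int(g.attrs["kx_taps"]),
            )
            weights = {}
            for key in g:
                if key.endswith("_real"):
                    d = int(key[len("offset") : -len("_real")])
                    weights[d] = g[key][()] + 1j * g[key[:-5] + "_imag"][()]
            return GrappaWeights(spec=spec, n_coils=int(g.attrs["n_coils"]), weights=weights)
        spec = build_network(method, int(g.attrs["n_coils"]))
        def read_layers(prefix, n):
            out = []
            for i in range(n):
                W = g[f"{prefix}{i}_W"][()]
                b = g[f"{prefix}{i}_b"][()] if f"{prefix}{i}_b" in g else None
                out.append((W, b))
            return tuple(out)
        prov = {
            k[len("prov_") :]: g.attrs[k] for k in g.attrs if k.startswith("prov_")
        }
        return WeightSet(
            method=method,
            spec=spec,
            layers=read_layers("layer", len(spec.layers)),
            linear_layers=read_layers("linear", len(spec.linear_layers)),
            norm=NormalizationRecord(scale=float(g.attrs["scale"])),
            provenance=prov,
            loss_trace=g["loss_trace"][()] if "loss_trace" in g else None,
        )
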