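"""File formats: HDF5 raw k-space container, NIfTI cine stacks.

Container layout (HDF5):
    /kspace      complex (n_coils, n_lines, n_readout)
    /line_table  compound (slice, pe, t_ms)
    /navigator   complex (n_lines,)
    /noise_cov   complex (n_coils, n_coils)
    /protocol    group attributes (one per protocol field)
    /binned      optional group written by the gating stage

Round trips are bit-exact for all arrays.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import nibabel as nib

from .containers import BinnedKSpace, CineStack, KSpaceSeries, LINE_TABLE_DTYPE
from .protocol import AcquisitionProtocol

FORMAT_VERSION = 1


class ContainerError(IOError):
    pass


def write_kspace_container(series: KSpaceSeries, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("kspace", data=series.data)
        f.create_dataset("line_table", data=series.line_table)
        f.create_dataset("navigator", data=series.navigator)
        f.create_dataset("noise_cov", data=np.asarray(series.noise_cov,
                                                      dtype=np.complex128))
        g = f.create_group("protocol")
        for k, v in series.protocol.to_dict().items():
            g.attrs[k] = v
        if "pattern" in series.meta:
            f.create_dataset("pattern", data=np.asarray(series.meta["pattern"]))
        for k in ("heart_rate_bpm", "resp_rate_bpm"):
            if k in series.meta:
                f.attrs[k] = series.meta[k]
    return path


def _protocol_from_attrs(attrs) -> AcquisitionProtocol:
    kw = {}
    for k, v in attrs.items():
        if isinstance(v, np.ndarray):
            v = tuple(v.tolist())
        elif isinstance(v, bytes):
            v = v.decode()
        elif isinstance(v, np.generic):
            v = v.item()
        kw[k] = v
    kw["matrix"] = tuple(int(x) for x in kw["matrix"])
    kw["fov_mm"] = tuple(float(x) for x in kw["fov_mm"])
    return AcquisitionProtocol(**kw)


def read_kspace_container(path) -> KSpaceSeries:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for ds in ("kspace", "line_table", "navigator", "noise_cov"):
            if ds not in f:
                raise ContainerError(f"container missing dataset /{ds}")
        if "protocol" not in f:
            raise ContainerError("container missing /protocol attributes")
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ContainerError(f"container format version {version} not "
                                 f"supported (expected {FORMAT_VERSION})")
        meta = {}
        if "pattern" in f:
            meta["pattern"] = f["pattern"][()]
        for k in ("heart_rate_bpm", "resp_rate_bpm"):
            if k in f.attrs:
                meta[k] = float(f.attrs[k])
        return KSpaceSeries(
            data=f["kspace"][()],
            line_table=f["line_table"][()].astype(LINE_TABLE_DTYPE),
            navigator=f["navigator"][()],
            protocol=_protocol_from_attrs(f["protocol"].attrs),
            noise_cov=f["noise_cov"][()],
            meta=meta,
        )


def write_binned(binned: BinnedKSpace, path) -> Path:
    """Store gated k-space under /binned of an existing container."""
    path = Path(path)
    with h5py.File(path, "a") as f:
        if "binned" in f:
            del f["binned"]
        g = f.create_group("binned")
        g.create_dataset("data", data=binned.data)
        g.create_dataset("hits", data=binned.hits)
        g.create_dataset("pattern", data=binned.pattern)
        rep = binned.fill_report
        g.create_dataset("fill_report",
                         data=rep.to_records(index=False) if len(rep)
                         else np.empty(0))
    return path


def read_binned(path) -> BinnedKSpace:
    import pandas as pd

    with h5py.File(path, "r") as f:
        if "binned" not in f:
            raise ContainerError("container has no /binned group (run gating first)")
        g = f["binned"]
        rep_raw = g["fill_report"][()]
        rep = (pd.DataFrame.from_records(rep_raw) if rep_raw.size
               else pd.DataFrame(columns=["frame", "slice", "pe", "source_line",
                                          "phase_distance"]))
        return BinnedKSpace(data=g["data"][()], hits=g["hits"][()],
                            pattern=g["pattern"][()], fill_report=rep)


# ---------------------------------------------------------------------------
# NIfTI cine
# ---------------------------------------------------------------------------

def write_cine(cine: CineStack, path) -> Path:
    """Cine as NIfTI (x, y, slice, frame) with voxel dims in the header;
    g maps in a sibling ``*_gmap.nii`` file."""
    path = Path(path)
    vy, vx, vz = cine.voxel_mm
    # internal (frame, slice, y, x) -> nifti (x, y, slice, frame)
    data = np.transpose(cine.frames, (3, 2, 1, 0)).astype(np.float32)
    affine = np.diag([vx, vy, vz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((vx, vy, vz, 1.0))
    nib.save(img, path)
    if cine.g_maps is not None:
        g = np.transpose(cine.g_maps, (2, 1, 0)).astype(np.float32)
        gimg = nib.Nifti1Image(g, np.diag([vx, vy, vz, 1.0]))
        gimg.header.set_zooms((vx, vy, vz))
        nib.save(gimg, _gmap_path(path))
    return path


def _gmap_path(path: Path) -> Path:
    suffix = "".join(path.suffixes)
    stem = path.name[: -len(suffix)] if suffix else path.name
    return path.with_name(stem + "_gmap" + (suffix or ".nii"))


def read_cine(path) -> CineStack:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ContainerError("cine NIfTI must be 4D (x, y, slice, frame)")
    zx, zy, zz = img.header.get_zooms()[:3]
    frames = np.transpose(data, (3, 2, 1, 0))
    g_maps = None
    gpath = _gmap_path(path)
    if gpath.exists():
        g = np.asarray(nib.load(gpath).dataobj, dtype=np.float32)
        g_maps = np.transpose(g, (2, 1, 0))
        if g_maps.shape != frames.shape[1:]:
            raise ContainerError("g map dimensions do not match the cine")
    return CineStack(frames=frames, voxel_mm=(float(zy), float(zx), float(zz)),
                     g_maps=g_maps)
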