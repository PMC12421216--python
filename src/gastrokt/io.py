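"""File formats: NIfTI-1 image series and the HDF5 k-space container.

Image series are written as 4D NIfTI-1 with voxel spacing in the header and
frame times in a sidecar JSON (``<stem>.frametimes.json``); k-space series
use an HDF5 container with ``kspace`` (complex, kx x ky x slice x time),
``mask`` (bool, ky x slice x time), ``frame_times`` (s), and acquisition
metadata as attributes.  Both round-trip losslessly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .types import ImageSeries, KSpaceSeries

__all__ = [
    "write_image_series",
    "read_image_series",
    "write_kspace",
    "read_kspace",
]

SCHEMA_VERSION = "1.0"


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".frametimes.json")
    return path.with_suffix(".frametimes.json")


def write_image_series(series: ImageSeries, path) -> Path:
    """Write a 4D NIfTI plus the frame-times sidecar JSON; returns the image path."""
    path = Path(path)
    affine = np.diag([*series.voxel_size, 1.0])
    img = nib.Nifti1Image(series.values.astype(np.float64), affine)
    zooms = list(series.voxel_size)
    dt = float(np.median(np.diff(series.frame_times))) if series.n_frames > 1 else 1.0
    img.header.set_zooms((*zooms, dt))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = {
        "frame_times_s": series.frame_times.tolist(),
        "voxel_size_mm": list(series.voxel_size),
        "provenance": series.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image_series(path) -> ImageSeries:
    """Read a 4D NIfTI written by :func:`write_image_series` (or compatible).

    Frame times come from the sidecar JSON; if it is missing they are derived
    from the header repetition time with a warning.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(
            f"expected a 4D (x, y, slice, time) NIfTI, got ndim={data.ndim}; "
            "stack frames into a 4D volume first"
        )
    zooms = img.header.get_zooms()
    if len(zooms) < 3 or any(z <= 0 for z in zooms[:3]):
        raise ValueError("missing or invalid voxel spacing in the NIfTI header")
    voxel = tuple(float(z) for z in zooms[:3])
    sidecar = _sidecar_path(path)
    provenance = ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_times = np.asarray(meta["frame_times_s"], float)
        provenance = meta.get("provenance", "")
    else:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        warnings.warn(
            f"no frame-times sidecar next to {path.name}; using header TR={tr} s",
            stacklevel=2,
        )
        frame_times = tr * np.arange(data.shape[3])
    return ImageSeries(data.astype(float), voxel, frame_times, provenance)


def write_kspace(kspace: KSpaceSeries, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.values.astype(np.complex128))
        f.create_dataset("mask", data=kspace.mask)
        f.create_dataset("frame_times", data=kspace.frame_times)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["voxel_size_mm"] = list(kspace.voxel_size)
        f.attrs["meta"] = json.dumps(kspace.attrs, default=str)
    return path


def read_kspace(path) -> KSpaceSeries:
    """Read the HDF5 k-space container; a missing mask means fully sampled."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        values = f["kspace"][()]
        if not np.iscomplexobj(values):
            raise ValueError("kspace dataset must be complex-valued")
        if "mask" in f:
            mask = f["mask"][()].astype(bool)
        else:
            warnings.warn("no mask dataset: treating k-space as fully sampled", stacklevel=2)
            mask = np.ones(values.shape[1:], dtype=bool)
        if "frame_times" in f:
            frame_times = f["frame_times"][()]
        else:
            frame_times = np.arange(values.shape[3], dtype=float)
        voxel = tuple(float(v) for v in f.attrs.get("voxel_size_mm", (1.0, 1.0, 1.0)))
        attrs = json.loads(f.attrs.get("meta", "{}"))
    return KSpaceSeries(values, mask, voxel, frame_times, attrs)
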