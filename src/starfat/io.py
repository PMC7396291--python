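"""Raw-data container (HDF5), parameter-map output (NIfTI), run reports (JSON).

The raw container holds k-space, trajectory, timing, calibration spokes and
self-gating results under a versioned schema.  NIfTI volumes carry voxel
size and units in the header description.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .containers import RadialKSpace
from .trajectory import CalibSpokes, Trajectory

SCHEMA_VERSION = 1


def write_raw(path, data: RadialKSpace, navigator=None, bins=None) -> None:
    """Write a RadialKSpace container to HDF5.

    Self-gating results (a RespSignal and/or BinAssignment) are stored
    under /selfgating when provided.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("kspace", data=data.samples, compression=None)
        t = data.traj
        g = f.create_group("traj")
        g.create_dataset("kx", data=t.kx)
        g.create_dataset("ky", data=t.ky)
        g.create_dataset("t_sample", data=t.t_sample)
        g.create_dataset("view_angle", data=t.view_angle)
        g.create_dataset("te", data=t.te)
        g.create_dataset("shift_per_echo", data=t.shift_per_echo)
        if data.calib is not None:
            f.create_dataset("calib", data=data.calib.lines)
        if navigator is not None or bins is not None:
            sg = f.create_group("selfgating")
            if navigator is not None:
                sg.create_dataset("amplitude_per_view", data=navigator.amplitude_per_view)
                sg.attrs["quality"] = navigator.quality
                sg.attrs["motion_detected"] = navigator.motion_detected
            if bins is not None:
                sg.create_dataset("bin_of_view", data=bins.bin_of_view)
                sg.attrs["n_bin"] = bins.n_bin
        meta = f.create_group("meta")
        for key, val in data.meta.items():
            if isinstance(val, np.ndarray):
                meta.create_dataset(key, data=val)
            elif val is not None:
                meta.attrs[key] = val


def read_raw(path) -> RadialKSpace:
    """Read a RadialKSpace container; raises on schema mismatch."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"raw container schema version {version} != expected {SCHEMA_VERSION}"
            )
        g = f["traj"]
        traj = Trajectory(
            kx=g["kx"][()],
            ky=g["ky"][()],
            t_sample=g["t_sample"][()],
            view_angle=g["view_angle"][()],
            te=g["te"][()],
            shift_per_echo=g["shift_per_echo"][()],
        )
        calib = CalibSpokes(lines=f["calib"][()]) if "calib" in f else None
        meta = {}
        if "selfgating" in f and "amplitude_per_view" in f["selfgating"]:
            meta["navigator_amplitude"] = f["selfgating/amplitude_per_view"][()]
        if "meta" in f:
            meta.update({k: v for k, v in f["meta"].attrs.items()})
            for k in f["meta"]:
                meta[k] = f["meta"][k][()]
        return RadialKSpace(samples=f["kspace"][()], traj=traj, calib=calib, meta=meta)


def write_maps(
    out_dir,
    name: str,
    volume: np.ndarray,
    voxel_size_mm=(1.0, 1.0, 1.0),
    units: str = "",
) -> Path:
    """Write a (possibly per-bin) real map as NIfTI; returns the file path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol = np.asarray(volume)
    if np.iscomplexobj(vol):
        vol = np.abs(vol)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    img.header["descrip"] = units.encode()[:79]
    path = out_dir / f"{name}.nii"
    nib.save(img, str(path))
    return path


def write_report(path, report: dict) -> None:
    """Machine-readable JSON run report."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(report, f, indent=2, default=default)
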