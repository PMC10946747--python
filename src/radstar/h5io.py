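"""HDF5 container for k-space data + trajectory (+ optional ground truth),
NIfTI export of parameter maps, and JSON sidecars for delays / cost traces.

Container layout (schema version 1)::

    /kspace                  complex, (echo, coil, spoke, readout)
    /traj/angles             (echo, spoke) degrees
    /traj/k                  (echo, spoke, readout, 2) cycles/FOV
    /traj/polarity           (echo,)
    /truth/{labels,t2star,m0,sens}   optional ground-truth group
    attrs: schema_version, echo_times_ms, dk_sample, grid_size, seed, ...
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .encoding import KSpaceData
from .phantom import CoilSensitivities, TissuePhantom
from .recon import ParameterMaps
from .trajectory import DelaySet, RadialTrajectory

SCHEMA_VERSION = 1


def write_container(
    path,
    data: KSpaceData,
    traj: RadialTrajectory,
    truth: TissuePhantom | None = None,
    sens: CoilSensitivities | None = None,
    attrs: dict | None = None,
) -> None:
    if data.samples.shape[0] != traj.k.shape[0] or data.samples.shape[2:] != traj.k.shape[1:3]:
        raise ValueError("k-space data and trajectory shapes disagree")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["echo_times_ms"] = np.asarray(data.echo_times_ms, dtype=float)
        f.attrs["dk_sample"] = traj.dk_sample
        f.attrs["grid_size"] = traj.grid_size
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        f.create_dataset("kspace", data=data.samples.astype(np.complex64))
        g = f.create_group("traj")
        g.create_dataset("angles", data=traj.angles_deg)
        g.create_dataset("k", data=traj.k)
        g.create_dataset("polarity", data=traj.polarity)
        if truth is not None:
            t = f.create_group("truth")
            t.create_dataset("labels", data=truth.labels)
            if truth.t2star_ms is not None:
                t.create_dataset("t2star", data=truth.t2star_ms)
            if truth.m0 is not None:
                t.create_dataset("m0", data=truth.m0)
            if sens is not None:
                t.create_dataset("sens", data=sens.maps.astype(np.complex64))


def read_container(path):
    """Load ``(KSpaceData, RadialTrajectory, truth-or-None, sens-or-None)``."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported container schema version {version} "
                f"(this package reads version {SCHEMA_VERSION})"
            )
        te = np.asarray(f.attrs["echo_times_ms"], dtype=float)
        data = KSpaceData(
            samples=f["kspace"][()].astype(np.complex128), echo_times_ms=te
        )
        traj = RadialTrajectory(
            angles_deg=f["traj/angles"][()],
            k=f["traj/k"][()],
            polarity=f["traj/polarity"][()],
            dk_sample=float(f.attrs["dk_sample"]),
            grid_size=int(f.attrs["grid_size"]),
        )
        truth = sens = None
        if "truth" in f:
            t = f["truth"]
            truth = TissuePhantom(
                labels=t["labels"][()],
                t2star_ms=t["t2star"][()] if "t2star" in t else None,
                m0=t["m0"][()] if "m0" in t else None,
            )
            if "sens" in t:
                sens = CoilSensitivities(maps=t["sens"][()].astype(np.complex128))
    return data, traj, truth, sens


def export_maps(maps: ParameterMaps, path) -> None:
    """Write T2*/M0 as NIfTI next to a JSON sidecar with delays + cost trace.

    ``path`` is the T2* output (e.g. ``maps.nii.gz``); the M0 volume and the
    sidecar take derived names (``*_m0.nii.gz``, ``*.json``).
    """
    path = Path(path)
    stem = path.name
    for ext in (".nii.gz", ".nii"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    affine = np.eye(4)
    img = nib.Nifti1Image(maps.t2star_ms.astype(np.float32), affine)
    img.header["descrip"] = b"T2* map [ms]"
    nib.save(img, path)
    m0_img = nib.Nifti1Image(maps.m0.astype(np.float32), affine)
    m0_img.header["descrip"] = b"M0 map [a.u.]"
    nib.save(m0_img, path.with_name(stem + "_m0" + path.name[len(stem):]))
    sidecar = {
        "delays_dwell": {
            "odd": list(maps.delays_est.odd),
            "even": list(maps.delays_est.even),
        },
        "cost_trace": [float(c) for c in maps.cost_trace],
        "converged": bool(maps.converged),
    }
    path.with_name(stem + ".json").write_text(json.dumps(sidecar, indent=2))
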