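"""HDF5 container and NIfTI export.

Container layout (all complex data stored as paired real/imag datasets):

* ``/kspace/real``, ``/kspace/imag`` -- ``(J, N_x, N_y, N_z)`` float64
* ``/mask`` -- boolean acquisition mask with attributes ``R_y``, ``R_z``,
  ``acs_y``, ``acs_z`` (present only for masked data)
* root attributes ``J``, ``deltas`` and optional free-form ``config`` JSON
  and ``seed``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .containers import MultiCoilKSpace
from .sampling import SamplingMask, SamplingScheme

__all__ = ["save_kspace", "load_kspace", "save_nifti_magnitude", "save_nifti_complex"]


def save_kspace(path, kspace: MultiCoilKSpace, config: dict | None = None,
                seed: int | None = None) -> None:
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("kspace")
        grp.create_dataset("real", data=kspace.data.real)
        grp.create_dataset("imag", data=kspace.data.imag)
        fh.attrs["J"] = kspace.J
        fh.attrs["deltas"] = np.asarray(kspace.deltas, dtype=float)
        if config is not None:
            fh.attrs["config"] = json.dumps(config)
        if seed is not None:
            fh.attrs["seed"] = int(seed)
        if kspace.mask is not None:
            ds = fh.create_dataset("mask", data=kspace.mask.mask)
            sch = kspace.mask.scheme
            ds.attrs["R_y"] = sch.R_y
            ds.attrs["R_z"] = sch.R_z
            ds.attrs["acs_y"] = sch.acs_y
            ds.attrs["acs_z"] = sch.acs_z


def load_kspace(path) -> MultiCoilKSpace:
    with h5py.File(path, "r") as fh:
        data = fh["kspace/real"][()] + 1j * fh["kspace/imag"][()]
        deltas = tuple(fh.attrs.get("deltas", (1.0, 1.0, 1.0)))
        mask = None
        if "mask" in fh:
            ds = fh["mask"]
            scheme = SamplingScheme(int(ds.attrs["R_y"]), int(ds.attrs["R_z"]),
                                    int(ds.attrs["acs_y"]), int(ds.attrs["acs_z"]),
                                    tuple(ds.shape))
            mask = SamplingMask(ds[()], scheme)
    return MultiCoilKSpace(data, deltas, mask)


def _affine(voxel_mm) -> np.ndarray:
    aff = np.diag(list(voxel_mm) + [1.0])
    return aff


def save_nifti_magnitude(path, volume: np.ndarray,
                         voxel_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a real 3D volume (or magnitude of a complex one) as NIfTI-1."""
    vol = np.abs(np.asarray(volume)).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, _affine(voxel_mm)), str(path))


def save_nifti_complex(path_stem, volume: np.ndarray,
                       voxel_mm=(1.0, 1.0, 1.0)) -> tuple[Path, Path]:
    """Write a complex 3D volume as a magnitude/phase NIfTI pair."""
    stem = Path(path_stem)
    mag_path = stem.with_name(stem.name + "_mag.nii.gz")
    phs_path = stem.with_name(stem.name + "_phase.nii.gz")
    vol = np.asarray(volume)
    nib.save(nib.Nifti1Image(np.abs(vol).astype(np.float32), _affine(voxel_mm)),
             str(mag_path))
    nib.save(nib.Nifti1Image(np.angle(vol).astype(np.float32), _affine(voxel_mm)),
             str(phs_path))
    return mag_path, phs_path
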