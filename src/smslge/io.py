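"""File I/O helpers: NIfTI images, JSON reports, HDF5 k-space."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .sms_encode import KSpaceData

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_json",
    "save_kspace_h5",
    "load_kspace_h5",
]


def save_nifti(
    path: str | Path,
    volume: np.ndarray,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    slice_thickness: float = 1.0,
) -> Path:
    """Write a (ny, nx) or (n_slices, ny, nx) real array as NIfTI.

    The affine is diagonal in the pixel spacings; slices map to the third
    NIfTI axis.
    """
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim == 2:
        vol = vol[None]
    # NIfTI expects (x, y, z)
    data = np.transpose(vol, (2, 1, 0))
    affine = np.diag(
        [pixel_spacing[1], pixel_spacing[0], slice_thickness, 1.0]
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def load_nifti(path: str | Path) -> np.ndarray:
    """Load a NIfTI written by :func:`save_nifti` back to (n_slices, ny, nx)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    return np.transpose(data, (2, 1, 0))


def save_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def save_kspace_h5(path: str | Path, reps: list[KSpaceData]) -> Path:
    """Serialize a repetition series of k-space data to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for i, rep in enumerate(reps):
            g = f.create_group(f"rep{i:03d}")
            g.create_dataset("data", data=rep.data)
            g.create_dataset("mask", data=rep.mask)
            g.attrs["rep_index"] = rep.rep_index
            g.attrs["R"] = rep.R
            g.attrs["phase_increment_slice1"] = rep.caipi[
                "phase_increment_slice1"
            ]
            g.attrs["phase_increment_slice2"] = rep.caipi[
                "phase_increment_slice2"
            ]
    return path


def load_kspace_h5(path: str | Path) -> list[KSpaceData]:
    reps = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            reps.append(
                KSpaceData(
                    data=np.asarray(g["data"]),
                    mask=np.asarray(g["mask"], dtype=bool),
                    rep_index=int(g.attrs["rep_index"]),
                    R=int(g.attrs["R"]),
                    caipi={
                        "phase_increment_slice1": float(
                            g.attrs["phase_increment_slice1"]
                        ),
                        "phase_increment_slice2": float(
                            g.attrs["phase_increment_slice2"]
                        ),
                    },
                )
            )
    return reps
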