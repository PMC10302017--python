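"""File I/O: NIfTI images, b-vector/b-value tables, k-space archives,
sampling masks, displacement fields, and landmark lists."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .phantoms import DWIStack
from .recon import KSpace
from .sampling import SamplingMask, Trajectory


# -- NIfTI ------------------------------------------------------------------


def save_nifti(path, array: np.ndarray, voxel_size: float = 1.0) -> None:
    arr = np.asarray(array, dtype=np.float32)
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_dwi_stack(stack: DWIStack, out_dir, basename: str = "dwi") -> dict:
    """Write images as NIfTI (H, W, n_dir) plus plain-text bvec/bval tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol = np.moveaxis(stack.images, 0, -1)
    nii = out / f"{basename}.nii"
    save_nifti(nii, vol)
    bvec = out / f"{basename}.bvec"
    np.savetxt(bvec, stack.q_vectors.T, fmt="%.8f")  # 3 x N
    bval = out / f"{basename}.bval"
    np.savetxt(bval, np.full((1, stack.n_directions), stack.b_value), fmt="%.1f")
    return {"nifti": str(nii), "bvec": str(bvec), "bval": str(bval)}


def load_dwi_stack(nii_path, bvec_path, bval_path) -> DWIStack:
    vol = load_nifti(nii_path)
    images = np.moveaxis(vol, -1, 0)
    q = np.loadtxt(bvec_path).T
    b = float(np.atleast_1d(np.loadtxt(bval_path)).ravel()[0])
    return DWIStack(images=images, q_vectors=np.atleast_2d(q), b_value=b)


# -- k-space ----------------------------------------------------------------


def save_kspace(path, kspace: KSpace) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("values", data=kspace.values)
        f.attrs["grid_size"] = list(kspace.grid_size)
        if isinstance(kspace.support, SamplingMask):
            f.create_dataset("mask", data=kspace.support.mask)
            f.attrs["hermitian_half"] = bool(kspace.support.hermitian_half)
        elif isinstance(kspace.support, Trajectory):
            f.create_dataset("coords", data=kspace.support.coords)
            f.create_dataset("density_weights", data=kspace.support.density_weights)


def load_kspace(path) -> KSpace:
    with h5py.File(str(path), "r") as f:
        values = f["values"][()]
        grid = tuple(int(g) for g in f.attrs["grid_size"])
        support = None
        if "mask" in f:
            support = SamplingMask(
                mask=f["mask"][()], hermitian_half=bool(f.attrs.get("hermitian_half", False))
            )
        elif "coords" in f:
            support = Trajectory(
                coords=f["coords"][()],
                density_weights=f["density_weights"][()],
                grid_size=grid[0],
            )
    return KSpace(values=values, support=support, grid_size=grid)


# -- masks ------------------------------------------------------------------


def save_mask(path_base, mask: SamplingMask) -> dict:
    """Array archive plus a JSON sidecar with grid size, fraction and flags."""
    base = Path(path_base)
    npz = base.with_suffix(".npz")
    np.savez_compressed(npz, mask=mask.mask)
    sidecar = base.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "grid_size": list(mask.grid_size),
                "fraction_sampled": mask.fraction_sampled,
                "hermitian_half": mask.hermitian_half,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {"npz": str(npz), "json": str(sidecar)}


def load_mask(path_base) -> SamplingMask:
    base = Path(path_base)
    data = np.load(base.with_suffix(".npz"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return SamplingMask(mask=data["mask"], hermitian_half=meta["hermitian_half"])


# -- displacement fields ----------------------------------------------------


def save_field(path, field: np.ndarray) -> None:
    np.savez_compressed(Path(path), field=np.asarray(field))


def load_field(path) -> np.ndarray:
    return np.load(Path(path))["field"]


# -- landmarks --------------------------------------------------------------


def save_landmarks(path, landmarks: np.ndarray) -> None:
    """One ``x y [z]`` line per landmark, 0-based voxel coordinates.

    Internally landmarks are (row, col[, z]); files store x=col, y=row.
    """
    lm = np.atleast_2d(np.asarray(landmarks, dtype=float))
    out = lm.copy()
    out[:, [0, 1]] = lm[:, [1, 0]]
    np.savetxt(str(path), out, fmt="%.6f")


def load_landmarks(path) -> np.ndarray:
    lm = np.atleast_2d(np.loadtxt(str(path)))
    out = lm.copy()
    out[:, [0, 1]] = lm[:, [1, 0]]
    return out
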