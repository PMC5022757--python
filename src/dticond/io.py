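"""NIfTI and table I/O.

Volumes are written with a diagonal affine built from the voxel size and the
axis-semantics tag (x = L→R, y = A→P, z = H→F) recorded in the NIfTI
description field.  Conductivity tensors are exported as flat CSV or JSON
records carrying full provenance: the nine entries, the baseline σ, the
source anisotropy vector, the Euler angles and the rotation convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import read_bval_bvec
from .rotation import ConductivityTensor
from .tensor import AXIS_SEMANTICS, AxisMap, DWIVolume, LabelMask, ScalarMap, TensorField

Volume = Union[DWIVolume, LabelMask, ScalarMap, AxisMap, TensorField]


class IOValidationError(ValueError):
    """Raised for malformed or inconsistent on-disk inputs."""


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def read_dwi_dataset(
    dwi_path: str | Path, bval_path: str | Path, bvec_path: str | Path
) -> DWIVolume:
    """Read a 4-D NIfTI DWI with its bval/bvec gradient table."""
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise IOValidationError(f"expected a 4-D DWI volume, got {data.ndim}-D")
    scheme = read_bval_bvec(bval_path, bvec_path)
    if len(scheme) != data.shape[3]:
        raise IOValidationError(
            f"gradient table length ({len(scheme)}) does not match the number "
            f"of volumes ({data.shape[3]})"
        )
    if scheme.n_b0 < 1:
        raise IOValidationError("gradient table contains no b=0 entry")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWIVolume(data, voxel_size, scheme)


def read_label_mask(path: str | Path) -> LabelMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMask(np.round(data).astype(np.int16), voxel_size)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI, refusing when grid metadata is missing."""
    voxel_size = getattr(volume, "voxel_size", None)
    if voxel_size is None or len(voxel_size) != 3 or any(v <= 0 for v in voxel_size):
        raise IOValidationError("cannot write a volume without positive 3-D voxel-size metadata")
    if isinstance(volume, DWIVolume):
        data = volume.signal
    elif isinstance(volume, LabelMask):
        data = volume.labels.astype(np.int16)
    elif isinstance(volume, (ScalarMap, AxisMap)):
        data = volume.data
    elif isinstance(volume, TensorField):
        data = volume.components
    else:
        raise IOValidationError(f"unsupported volume type {type(volume).__name__}")
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    img.header["descrip"] = AXIS_SEMANTICS.encode()
    img.header.set_zooms(tuple(voxel_size) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def read_scalar_map(path: str | Path, kind: str) -> ScalarMap:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarMap(np.asarray(img.dataobj, dtype=float), kind, voxel_size)


def read_axis_map(path: str | Path) -> AxisMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 3:
        raise IOValidationError("axis map must be stored as a 4-D volume with 3 components")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return AxisMap(data, voxel_size)


def _tensor_record(t: ConductivityTensor, case: str | None = None) -> dict:
    rec = {
        "case": case if case is not None else "",
        "tissue": t.tissue if t.tissue is not None else "",
        "sigma_S_per_m": t.sigma,
    }
    for i in range(3):
        for j in range(3):
            rec[f"m{i + 1}{j + 1}"] = float(t.matrix[i, j])
    ax, ay, az = t.source.source.components
    rec.update(
        {
            "Ax": ax,
            "Ay": ay,
            "Az": az,
            "alpha_deg": t.source.angles.alpha,
            "theta_deg": t.source.angles.theta,
            "phi_deg": t.source.angles.phi,
            "symmetric": t.source.symmetric,
            "convention": t.source.convention,
        }
    )
    return rec


def export_tensor_table(
    tensors: list[ConductivityTensor],
    path: str | Path,
    cases: list[str] | None = None,
) -> None:
    """Export conductivity tensors as CSV or JSON (chosen by file suffix)."""
    if not tensors:
        raise IOValidationError("refusing to export an empty tensor list")
    if cases is None:
        cases = [None] * len(tensors)
    records = [_tensor_record(t, c) for t, c in zip(tensors, cases)]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def import_tensor_table(path: str | Path) -> pd.DataFrame:
    """Re-import an exported tensor table at full stored precision."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)


def tensor_matrix_from_record(rec) -> np.ndarray:
    """Rebuild the 3×3 matrix from one imported table record."""
    return np.array([[rec[f"m{i + 1}{j + 1}"] for j in range(3)] for i in range(3)], dtype=float)
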