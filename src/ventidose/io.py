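"""Reading and writing volumes (NIfTI / MetaImage) and cohort tables (CSV).

NIfTI is handled through nibabel with a diagonal affine (spacing on the
diagonal, origin in the translation column). MetaImage (.mha/.mhd) goes
through SimpleITK. Displacement fields follow the NIfTI vector convention:
a 5-D volume of dim (nx, ny, nz, 1, 3) with intent code VECTOR (1007);
4-D (nx, ny, nz, 3) files are accepted on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .grids import DisplacementField, DoseGrid, ImageGrid, StructureMask

__all__ = [
    "read_image",
    "write_image",
    "read_dose",
    "write_dose",
    "read_mask",
    "write_mask",
    "read_displacement_field",
    "write_displacement_field",
    "read_cohort",
    "write_cohort",
    "FV_COLUMNS",
    "OUTCOME_COLUMN",
]

FV_COLUMNS = [f"V{x}" for x in range(5, 65, 5)]
OUTCOME_COLUMN = "rp_grade2plus"

NIFTI_INTENT_VECTOR = 1007


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _is_metaimage(path: str) -> bool:
    return path.endswith(".mha") or path.endswith(".mhd")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _read_scalar(path: str):
    if _is_nifti(path):
        img = nib.load(path)
        arr = np.asarray(img.dataobj, dtype=float)
        aff = img.affine
        spacing = tuple(np.abs(np.diag(aff)[:3]))
        origin = tuple(aff[:3, 3])
        return np.squeeze(arr), spacing, origin
    if _is_metaimage(path):
        img = sitk.ReadImage(path)
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        arr = np.transpose(arr, (2, 1, 0)).astype(float)
        return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())
    raise ValueError(f"unsupported volume format: {path}")


def _write_scalar(arr: np.ndarray, spacing, origin, path: str, dtype=None) -> None:
    if dtype is not None:
        arr = arr.astype(dtype)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr, _affine(spacing, origin)), path)
        return
    if _is_metaimage(path):
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0))))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, path)
        return
    raise ValueError(f"unsupported volume format: {path}")


def read_image(path: str) -> ImageGrid:
    arr, spacing, origin = _read_scalar(path)
    return ImageGrid(values=arr, spacing=spacing, origin=origin)


def write_image(grid: ImageGrid, path: str) -> None:
    _write_scalar(grid.values, grid.spacing, grid.origin, path)


def read_dose(path: str) -> DoseGrid:
    arr, spacing, origin = _read_scalar(path)
    return DoseGrid(dose=arr, spacing=spacing, origin=origin)


def write_dose(grid: DoseGrid, path: str) -> None:
    _write_scalar(grid.dose, grid.spacing, grid.origin, path)


def read_mask(path: str, name: str = "structure") -> StructureMask:
    arr, spacing, origin = _read_scalar(path)
    return StructureMask(inside=arr > 0.5, spacing=spacing, origin=origin, name=name)


def write_mask(mask: StructureMask, path: str) -> None:
    _write_scalar(mask.inside, mask.spacing, mask.origin, path, dtype=np.uint8)


def read_displacement_field(path: str) -> DisplacementField:
    if _is_nifti(path):
        img = nib.load(path)
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim == 5 and arr.shape[3] == 1:
            arr = arr[:, :, :, 0, :]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"not a 3-component vector volume: shape {arr.shape}")
        aff = img.affine
        return DisplacementField(
            vectors=arr,
            spacing=tuple(np.abs(np.diag(aff)[:3])),
            origin=tuple(aff[:3, 3]),
        )
    if _is_metaimage(path):
        img = sitk.ReadImage(path)
        arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
        arr = np.transpose(arr, (2, 1, 0, 3)).astype(float)
        return DisplacementField(
            vectors=arr, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin())
        )
    raise ValueError(f"unsupported volume format: {path}")


def write_displacement_field(field: DisplacementField, path: str) -> None:
    if _is_nifti(path):
        arr = field.vectors[:, :, :, np.newaxis, :]  # (nx, ny, nz, 1, 3)
        img = nib.Nifti1Image(arr, _affine(field.spacing, field.origin))
        img.header.set_intent(NIFTI_INTENT_VECTOR)
        nib.save(img, path)
        return
    if _is_metaimage(path):
        arr = np.ascontiguousarray(np.transpose(field.vectors, (2, 1, 0, 3)))
        img = sitk.GetImageFromArray(arr, isVector=True)
        img.SetSpacing(tuple(float(s) for s in field.spacing))
        img.SetOrigin(tuple(float(o) for o in field.origin))
        sitk.WriteImage(img, path)
        return
    raise ValueError(f"unsupported volume format: {path}")


def read_cohort(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Load a cohort CSV with columns patient_id, V5..V60, rp_grade2plus."""
    table = pd.read_csv(path)
    missing = [c for c in FV_COLUMNS + [OUTCOME_COLUMN] if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    bad = set(np.unique(table[OUTCOME_COLUMN])) - {0, 1}
    if bad:
        raise ValueError(f"outcome column must be binary 0/1, found {sorted(bad)}")
    return table


def write_cohort(table: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    cols = ["patient_id"] + FV_COLUMNS + [OUTCOME_COLUMN]
    extra = [c for c in table.columns if c not in cols]
    table.loc[:, cols + extra].to_csv(path, index=False)
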