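"""Displacement vector fields: intensity-based demons registration and warping.

The registration stage is pluggable by design — any smooth displacement
field source (a precomputed field read from disk, or the demons routine
here) can feed the ventilation stage. ``register_demons`` wraps SimpleITK's
diffusive demons filter in a hand-rolled multi-resolution pyramid; the
returned field lives on the fixed grid and maps fixed-grid world points to
their corresponding moving-image locations, so ``warp_image(moving, field)``
aligns the moving image onto the fixed grid.
"""

from __future__ import annotations

import warnings
from typing import List

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .grids import DisplacementField, ImageGrid

__all__ = ["register_demons", "warp_image", "mse"]


def mse(a: ImageGrid, b: ImageGrid) -> float:
    """Mean squared intensity difference between two volumes on one grid."""
    a.require_same_geometry(b, "images")
    return float(np.mean((a.values - b.values) ** 2))


def warp_image(moving: ImageGrid, field: DisplacementField) -> ImageGrid:
    """Resample ``moving`` at the displaced points x + u(x) of the field grid.

    Trilinear interpolation; samples falling outside the moving grid take the
    nearest-edge value. The output lives on the field's (fixed) grid.
    """
    if moving.shape != field.shape:
        raise ValueError(
            f"shape mismatch: moving {moving.shape} vs field {field.shape}"
        )
    pts = field.world_grid() + field.vectors
    idx = (pts - np.asarray(moving.origin)) / np.asarray(moving.spacing)
    coords = [idx[..., a] for a in range(3)]
    out = map_coordinates(moving.values, coords, order=1, mode="nearest")
    return ImageGrid(values=out, spacing=field.spacing, origin=field.origin)


def _to_sitk(grid: ImageGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(grid.values, (2, 1, 0)), dtype=np.float64)
    )
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    smoothed = sitk.SmoothingRecursiveGaussian(
        img, [0.5 * factor * s for s in img.GetSpacing()]
    )
    return sitk.Shrink(smoothed, [factor] * 3)


def register_demons(
    fixed: ImageGrid,
    moving: ImageGrid,
    levels: int = 3,
    iterations_per_level: int = 50,
    smoothing_sigma_mm: float = 2.0,
) -> DisplacementField:
    """Multi-resolution diffusive demons registration.

    Runs a fixed iteration budget per pyramid level (coarse to fine, shrink
    factors 2^(levels-1) … 1) with Gaussian smoothing of the displacement
    field after every update. Deterministic: no stochastic sampling and no
    convergence-based early stop. If the final field does not reduce the mean
    squared intensity difference relative to the identity, the zero field is
    returned with a warning.
    """
    fixed.require_same_geometry(moving, "fixed and moving images")
    zero = DisplacementField(
        vectors=np.zeros(fixed.shape + (3,)), spacing=fixed.spacing, origin=fixed.origin
    )
    if np.ptp(fixed.values) == 0 or np.ptp(moving.values) == 0:
        warnings.warn(
            "constant-intensity input: the registration objective has no "
            "intensity gradient; returning the zero field",
            RuntimeWarning,
        )
        return zero

    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    factors = [2 ** (levels - 1 - k) for k in range(levels)]
    min_dim = min(fixed.shape)
    factors = [f for f in factors if min_dim // f >= 4] or [1]

    demons = sitk.DemonsRegistrationFilter()
    demons.SetNumberOfIterations(int(iterations_per_level))
    demons.SetSmoothDisplacementField(True)

    field_img = None
    for factor in factors:
        f_l, m_l = _shrink(f_img, factor), _shrink(m_img, factor)
        # demons field smoothing is specified in voxels; floor at one voxel,
        # below which the update field is too rough and the iteration diverges
        sigma_vox = smoothing_sigma_mm / float(np.mean(f_l.GetSpacing()))
        demons.SetStandardDeviations(max(sigma_vox, 1.0))
        if field_img is None:
            field_img = sitk.Image(f_l.GetSize(), sitk.sitkVectorFloat64, 3)
            field_img.CopyInformation(f_l)
        else:
            field_img = sitk.Resample(
                field_img, f_l, sitk.Transform(), sitk.sitkLinear
            )
        field_img = demons.Execute(f_l, m_l, field_img)

    if field_img.GetSize() != f_img.GetSize():
        field_img = sitk.Resample(field_img, f_img, sitk.Transform(), sitk.sitkLinear)

    arr = sitk.GetArrayFromImage(field_img)  # (z, y, x, 3), components (x, y, z)
    vectors = np.transpose(arr, (2, 1, 0, 3)).astype(float)
    field = DisplacementField(
        vectors=vectors, spacing=fixed.spacing, origin=fixed.origin
    )

    if mse(fixed, warp_image(moving, field)) > mse(fixed, moving):
        warnings.warn(
            "demons increased the mean squared difference; returning the zero field",
            RuntimeWarning,
        )
        return zero
    return field
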