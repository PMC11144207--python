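"""Jacobian ventilation maps and high-function lung (fLung) segmentation.

The local volume-change ratio of the breathing deformation φ(x) = x + u(x)
is J(x) = det(I + ∂u/∂x). J > 1 marks locally expanding (well-ventilated)
tissue; the high-function lung is segmented as lung voxels with J strictly
above a threshold, 1.2 by default. The threshold applies to the raw
Jacobian, not to a lung-mean-normalized value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import DisplacementField, StructureMask, _Gridded

__all__ = ["VentilationMap", "jacobian_determinant", "segment_high_function"]

logger = logging.getLogger(__name__)


@dataclass
class VentilationMap(_Gridded):
    """Dimensionless per-voxel volume-change ratio J = det(I + ∇u)."""

    jacobian: np.ndarray = field(default_factory=lambda: np.ones((1, 1, 1)))
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.jacobian = np.asarray(self.jacobian, dtype=float)
        if self.jacobian.ndim != 3:
            raise ValueError("jacobian must be 3-D")
        super().__post_init__()

    def _data(self) -> np.ndarray:
        return self.jacobian


def jacobian_determinant(dvf: DisplacementField) -> VentilationMap:
    """Spacing-aware Jacobian determinant of the deformation x + u(x).

    ∂u/∂x uses central differences in the interior and one-sided differences
    at the grid borders, so the determinant is exact (to rounding) for
    affine displacement fields. Non-positive determinants (local folding)
    are physically implausible but retained; their count is logged.
    """
    u = dvf.vectors
    if not np.all(np.isfinite(u)):
        bad = np.argwhere(~np.isfinite(u))[0]
        raise ValueError(
            f"displacement field has a non-finite component at voxel "
            f"({bad[0]}, {bad[1]}, {bad[2]}), component {bad[3]}"
        )
    # grad[i][j] = ∂u_i/∂x_j
    grad = [
        [np.gradient(u[..., i], dvf.spacing[j], axis=j) for j in range(3)]
        for i in range(3)
    ]
    f = [[grad[i][j] + (1.0 if i == j else 0.0) for j in range(3)] for i in range(3)]
    det = (
        f[0][0] * (f[1][1] * f[2][2] - f[1][2] * f[2][1])
        - f[0][1] * (f[1][0] * f[2][2] - f[1][2] * f[2][0])
        + f[0][2] * (f[1][0] * f[2][1] - f[1][1] * f[2][0])
    )
    n_nonpos = int(np.sum(det <= 0))
    if n_nonpos:
        logger.warning(
            "Jacobian map contains %d non-positive voxels (local folding)", n_nonpos
        )
    return VentilationMap(jacobian=det, spacing=dvf.spacing, origin=dvf.origin)


def segment_high_function(
    vent: VentilationMap,
    lung: StructureMask,
    threshold: float = 1.2,
    presmooth_sigma_mm: Optional[float] = None,
) -> StructureMask:
    """Segment the high-function lung: lung voxels with J strictly > threshold.

    ``presmooth_sigma_mm`` optionally Gaussian-smooths the Jacobian map
    before thresholding (off by default). Ties at exactly the threshold are
    excluded. The result is always a subset of the lung mask.
    """
    if not vent.same_geometry(lung):
        raise ValueError(
            f"ventilation map and lung mask must share grids: "
            f"{vent.shape}/{vent.spacing} vs {lung.shape}/{lung.spacing}"
        )
    jac = vent.jacobian
    if presmooth_sigma_mm is not None and presmooth_sigma_mm > 0:
        jac = gaussian_filter(
            jac, sigma=[presmooth_sigma_mm / s for s in vent.spacing]
        )
    inside = lung.inside & (jac > threshold)
    return StructureMask(
        inside=inside, spacing=vent.spacing, origin=vent.origin, name="fLung"
    )
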