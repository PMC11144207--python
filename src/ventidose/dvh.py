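"""Cumulative dose-volume histograms and the functional dose-volume vector.

Vx is the percentage of a structure's volume receiving at least x Gy
("≥ level", inclusive). The functional dose-volume vector collects V5, V10,
…, V60 evaluated on the high-function lung (fLung); these twelve
percentages are the covariates of the pneumonitis risk models. Volumes are
computed by voxel counting with uniform voxel volume — relative (percent)
values by default, absolute cubic centimetres behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .grids import DoseGrid, StructureMask, _Gridded

__all__ = [
    "DVHCurve",
    "FvVector",
    "FV_DOSE_LEVELS",
    "cumulative_dvh",
    "volume_at_dose",
    "extract_fv_vector",
    "resample_dose_to",
]

FV_DOSE_LEVELS = tuple(range(5, 65, 5))


@dataclass
class DVHCurve:
    """Cumulative DVH: percent of structure volume receiving ≥ each edge."""

    bin_edges: np.ndarray
    cumulative_percent: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cumulative_percent = np.asarray(self.cumulative_percent, dtype=float)
        if self.bin_edges.shape != self.cumulative_percent.shape:
            raise ValueError("bin_edges and cumulative_percent must match")

    def at(self, level: float) -> float:
        """Curve value at an arbitrary dose level (step interpolation)."""
        i = np.searchsorted(self.bin_edges, level, side="right") - 1
        return float(self.cumulative_percent[max(i, 0)])


@dataclass
class FvVector:
    """The 12 functional dose-volume covariates V5…V60, in percent of fLung."""

    v: Dict[int, float]

    def __post_init__(self) -> None:
        if tuple(sorted(self.v)) != FV_DOSE_LEVELS:
            raise ValueError(f"expected levels {FV_DOSE_LEVELS}, got {sorted(self.v)}")
        vals = [self.v[x] for x in FV_DOSE_LEVELS]
        if any(not (0.0 <= p <= 100.0) for p in vals):
            raise ValueError("entries must lie in [0, 100]")
        if any(a < b - 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError("Vx must be non-increasing in the dose level")

    def __getitem__(self, key) -> float:
        if isinstance(key, str):
            key = int(key.lstrip("Vv"))
        return self.v[key]

    def __contains__(self, key) -> bool:
        try:
            self[key]
            return True
        except KeyError:
            return False

    def as_series(self) -> pd.Series:
        return pd.Series({f"V{x}": self.v[x] for x in FV_DOSE_LEVELS})


def resample_dose_to(dose: DoseGrid, target: _Gridded) -> DoseGrid:
    """Trilinearly resample a dose grid onto another grid's geometry."""
    idx = (target.world_grid() - np.asarray(dose.origin)) / np.asarray(dose.spacing)
    vals = map_coordinates(
        dose.dose, [idx[..., a] for a in range(3)], order=1, mode="nearest"
    )
    return DoseGrid(
        dose=np.clip(vals, 0.0, None), spacing=target.spacing, origin=target.origin
    )


def _mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if mask.voxel_count == 0:
        raise ValueError(f"structure mask '{mask.name}' is empty")
    if not dose.same_geometry(mask):
        dose = resample_dose_to(dose, mask)
    return dose.dose[mask.inside]


def cumulative_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = 0.1
) -> DVHCurve:
    """Cumulative DVH of a structure by voxel counting.

    cumulative_percent(d) = 100 · |{mask voxels with dose ≥ d}| / |mask|,
    evaluated at bin edges 0, bin_width, 2·bin_width, … past the maximum
    dose (so the curve reaches 0%). Dose is resampled to the mask grid if
    the geometries differ.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = np.sort(_mask_doses(dose, mask))
    n = d.size
    n_bins = int(np.ceil(d[-1] / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    percent = 100.0 * (n - np.searchsorted(d, edges, side="left")) / n
    return DVHCurve(bin_edges=edges, cumulative_percent=percent)


def volume_at_dose(
    dose: DoseGrid, mask: StructureMask, level: float, absolute_cc: bool = False
) -> float:
    """Vx: fraction of the structure receiving ≥ level Gy (inclusive).

    Percent of structure volume by default; cubic centimetres when
    ``absolute_cc`` is set.
    """
    d = _mask_doses(dose, mask)
    count = int(np.count_nonzero(d >= level))
    if absolute_cc:
        return count * mask.voxel_volume_mm3 / 1000.0
    return 100.0 * count / d.size


def extract_fv_vector(dose: DoseGrid, flung: StructureMask) -> FvVector:
    """The functional dose-volume vector: V5…V60 in 5-Gy steps on fLung."""
    d = _mask_doses(dose, flung)
    return FvVector(
        v={x: 100.0 * int(np.count_nonzero(d >= x)) / d.size for x in FV_DOSE_LEVELS}
    )
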