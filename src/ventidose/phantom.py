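"""Synthetic breathing phantoms and simulated patient cohorts.

The phantom stands in for a 4D-CT acquisition: a pair of respiratory-phase
volumes (peak exhale / peak inhale) related by an analytically known
displacement field, together with a two-ellipsoid lung mask and a dose grid
with Gaussian falloff. Because both the exhale intensity model and the
breathing deformation are closed-form functions of world coordinates, the
inhale volume is evaluated *exactly* at displaced points — no interpolation
enters the ground truth — and the Jacobian of the deformation is available
analytically for validation.

The breathing model is a craniocaudally dominant displacement: amplitude is
largest near the diaphragm and decays exponentially toward the apex, and a
C¹ cosine window confines the motion to a bounded support box around the
lungs. An affine-field mode (``PhantomSpec.affine``) replaces the breathing
model with u(x) = A·(x − center), whose Jacobian det(I + A) is spatially
constant — the main closed-form oracle for the ventilation stage.

Cohort simulation draws correlated functional dose-volume covariates
(V5…V60) from a multivariate normal, clips them to [0, 100] and sorts each
row in descending order so that every draw is a valid cumulative DVH vector,
then assigns the binary pneumonitis outcome from a logistic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .grids import DisplacementField, DoseGrid, ImageGrid, StructureMask
from .io import FV_COLUMNS, OUTCOME_COLUMN
from .riskmodel import PUBLISHED_STEPWISE_MODEL, LogisticModel

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "CohortSimSpec",
    "generate_phantom_pair",
    "generate_dose_grid",
    "simulate_cohort",
    "DEFAULT_SEED",
]

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20240601


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in mm (world coords)."""

    center: Tuple[float, float, float]
    semi_axes: Tuple[float, float, float]

    def radius(self, points: np.ndarray) -> np.ndarray:
        """Normalized elliptic radius (1 on the surface) at (..., 3) points."""
        d = (points - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.sqrt((d**2).sum(axis=-1))


def _default_lungs(extent: np.ndarray) -> Tuple[Ellipsoid, Ellipsoid]:
    cx, cy, cz = extent / 2.0
    a = (0.16 * extent[0], 0.22 * extent[1], 0.34 * extent[2])
    left = Ellipsoid(center=(cx - 0.21 * extent[0], cy, cz), semi_axes=a)
    right = Ellipsoid(center=(cx + 0.21 * extent[0], cy, cz), semi_axes=a)
    return left, right


@dataclass
class PhantomSpec:
    """Parameters of the breathing phantom.

    motion_amplitude is the peak (diaphragm-level) displacement in mm;
    motion_decay is the dimensionless exponential falloff rate of that
    amplitude over the craniocaudal lung extent (0 = uniform motion).
    ``affine`` switches to the affine-field test mode.
    """

    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    spacing: Tuple[float, float, float] = (5.0, 5.0, 5.0)
    lung_geometry: Optional[Tuple[Ellipsoid, Ellipsoid]] = None
    motion_amplitude: float = 15.0
    motion_decay: float = 2.0
    noise_sd: float = 10.0
    seed: int = DEFAULT_SEED
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 8 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lung_geometry is None:
            self.lung_geometry = _default_lungs(self.extent)
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (3, 3):
                raise ValueError("affine must be a 3x3 matrix")
        self._validate_geometry()

    @property
    def extent(self) -> np.ndarray:
        """Physical extent of the grid in mm (voxel centers at 0 .. extent)."""
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing)

    def _validate_geometry(self) -> None:
        hi = self.extent
        for e in self.lung_geometry:
            c, a = np.asarray(e.center), np.asarray(e.semi_axes)
            if np.any(a <= 0):
                raise ValueError(f"ellipsoid semi-axes must be positive: {e}")
            if np.any(c - a < 0) or np.any(c + a > hi):
                raise ValueError(
                    f"degenerate geometry: lung ellipsoid {e} extends beyond the "
                    f"grid extent {hi} mm; shrink the ellipsoid or enlarge the grid"
                )

    # ---- support box of the motion (lung bounding box with margin) ----
    def motion_support(self) -> Tuple[np.ndarray, np.ndarray]:
        cs = np.array([e.center for e in self.lung_geometry])
        ax = np.array([e.semi_axes for e in self.lung_geometry])
        lo = (cs - ax).min(axis=0)
        hi = (cs + ax).max(axis=0)
        margin = 0.15 * (hi - lo)
        return np.maximum(lo - margin, 0.0), np.minimum(hi + margin, self.extent)


# ---------------------------------------------------------------------------
# analytic building blocks


def _window(s: np.ndarray, lo: float, hi: float, ramp: float):
    """C¹ cosine window on [lo, hi] with ramp width ``ramp``; returns (w, dw/ds)."""
    w = np.zeros_like(s)
    dw = np.zeros_like(s)
    t_lo = (s - lo) / ramp
    t_hi = (hi - s) / ramp
    core = (s >= lo + ramp) & (s <= hi - ramp)
    w[core] = 1.0
    rise = (s > lo) & (s < lo + ramp)
    w[rise] = np.sin(0.5 * np.pi * t_lo[rise]) ** 2
    dw[rise] = (0.5 * np.pi / ramp) * np.sin(np.pi * t_lo[rise])
    fall = (s > hi - ramp) & (s < hi)
    w[fall] = np.sin(0.5 * np.pi * t_hi[fall]) ** 2
    dw[fall] = -(0.5 * np.pi / ramp) * np.sin(np.pi * t_hi[fall])
    return w, dw


def _displacement_and_dz(spec: PhantomSpec, points: np.ndarray):
    """Breathing displacement u (..., 3) and its analytic ∂u_z/∂z."""
    u = np.zeros(points.shape)
    if spec.affine is not None:
        center = spec.extent / 2.0
        u = (points - center) @ spec.affine.T
        # for the affine mode ∂u/∂x is the matrix itself; return dzz component
        dzz = np.full(points.shape[:-1], spec.affine[2, 2])
        return u, dzz
    lo, hi = spec.motion_support()
    ramp = 0.3 * (hi - lo)
    wx, _ = _window(points[..., 0], lo[0], hi[0], ramp[0])
    wy, _ = _window(points[..., 1], lo[1], hi[1], ramp[1])
    wz, dwz = _window(points[..., 2], lo[2], hi[2], ramp[2])
    height = hi[2] - lo[2]
    t = np.clip((points[..., 2] - lo[2]) / height, 0.0, None)
    g = np.exp(-spec.motion_decay * t)
    dg = -(spec.motion_decay / height) * g
    amp = spec.motion_amplitude
    u[..., 2] = amp * wx * wy * wz * g
    dzz = amp * wx * wy * (dwz * g + wz * dg)
    return u, dzz


def _intensity(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Smooth HU-like exhale intensity model evaluated at world points."""
    left, right = spec.lung_geometry
    cs = np.array([left.center, right.center])
    ax = np.array([left.semi_axes, right.semi_axes])
    body_center = cs.mean(axis=0)
    body_axes = ((cs + ax).max(axis=0) - (cs - ax).min(axis=0)) / 2.0 * 1.35 + 10.0
    body = Ellipsoid(tuple(body_center), tuple(body_axes))

    eps = 0.08
    s_body = expit((1.0 - body.radius(points)) / eps)
    s_lung = expit((1.0 - left.radius(points)) / eps) + expit(
        (1.0 - right.radius(points)) / eps
    )
    texture = (
        25.0
        * np.sin(2 * np.pi * points[..., 0] / 37.0)
        * np.sin(2 * np.pi * points[..., 1] / 41.0)
        * np.sin(2 * np.pi * points[..., 2] / 43.0)
    )
    return -1000.0 + 950.0 * s_body + (-820.0 + texture) * s_lung


def generate_phantom_pair(
    spec: PhantomSpec,
) -> Tuple[ImageGrid, ImageGrid, DisplacementField, StructureMask]:
    """Generate (exhale, inhale, truth DVF, lung mask) for a breathing phantom.

    The inhale volume is the exhale intensity model sampled at x + u(x), so
    warping exhale through the truth field reproduces inhale up to the
    warper's interpolation error only. With ``noise_sd > 0`` independent
    Gaussian noise is added to each phase volume.
    """
    meta = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    grid = ImageGrid(values=np.zeros(spec.grid_shape), **meta)
    pts = grid.world_grid()

    u, _ = _displacement_and_dz(spec, pts)
    exhale_vals = _intensity(spec, pts)
    inhale_vals = _intensity(spec, pts + u)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        exhale_vals = exhale_vals + rng.normal(0.0, spec.noise_sd, exhale_vals.shape)
        inhale_vals = inhale_vals + rng.normal(0.0, spec.noise_sd, inhale_vals.shape)

    left, right = spec.lung_geometry
    lung = (left.radius(pts) <= 1.0) | (right.radius(pts) <= 1.0)

    return (
        ImageGrid(values=exhale_vals, **meta),
        ImageGrid(values=inhale_vals, **meta),
        DisplacementField(vectors=u, **meta),
        StructureMask(inside=lung, name="lung", **meta),
    )


def analytic_jacobian(spec: PhantomSpec) -> np.ndarray:
    """Exact Jacobian determinant of the phantom deformation on the grid.

    For the breathing model u = (0, 0, u_z) the determinant is 1 + ∂u_z/∂z;
    for the affine mode it is det(I + A) everywhere.
    """
    if spec.affine is not None:
        det = float(np.linalg.det(np.eye(3) + spec.affine))
        return np.full(spec.grid_shape, det)
    grid = ImageGrid(values=np.zeros(spec.grid_shape), spacing=spec.spacing)
    _, dzz = _displacement_and_dz(spec, grid.world_grid())
    return 1.0 + dzz


def generate_dose_grid(
    spec: PhantomSpec,
    target_center: Sequence[float],
    prescription: float,
    falloff_mm: float,
) -> DoseGrid:
    """Gaussian-falloff dose: prescription at the target, ~exp(-r²/2σ²) decay."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    if falloff_mm <= 0:
        raise ValueError("falloff_mm must be positive")
    center = np.asarray(target_center, dtype=float)
    if np.any(center < 0) or np.any(center > spec.extent):
        raise ValueError(
            f"target_center {center} lies outside the grid extent {spec.extent} mm"
        )
    grid = ImageGrid(values=np.zeros(spec.grid_shape), spacing=spec.spacing)
    r2 = ((grid.world_grid() - center) ** 2).sum(axis=-1)
    dose = prescription * np.exp(-r2 / (2.0 * falloff_mm**2))
    return DoseGrid(dose=dose, spacing=spec.spacing)


# ---------------------------------------------------------------------------
# cohort simulation

#: Default mean functional dose-volume percentages for V5..V60 (descending
#: cumulative profile). The V25 mean is placed so that the linear predictor of
#: the published risk model at the mean covariates sits near logit(16/41),
#: the grade-≥2 pneumonitis prevalence of the reference 41-patient cohort.
DEFAULT_COVARIATE_MEAN = np.array(
    [72.0, 64.0, 55.0, 47.0, 41.3, 31.0, 24.0, 18.0, 13.0, 9.0, 5.0, 2.0]
)


def default_covariate_covariance(sd: float = 15.0, rho: float = 0.9) -> np.ndarray:
    """AR(1)-correlated covariance over the 12 Vx covariates.

    Neighbouring dose levels of a cumulative DVH are strongly collinear; the
    0.9^|i-j| structure reproduces that multicollinearity, which is what makes
    the different variable selectors disagree on small cohorts.
    """
    idx = np.arange(12)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return sd * sd * corr


@dataclass
class CohortSimSpec:
    """Parameters of the simulated pneumonitis cohort."""

    n_patients: int = 41
    true_model: LogisticModel = field(default_factory=lambda: PUBLISHED_STEPWISE_MODEL)
    covariate_mean: np.ndarray = field(default_factory=lambda: DEFAULT_COVARIATE_MEAN.copy())
    covariate_covariance: np.ndarray = field(default_factory=default_covariate_covariance)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.covariate_mean = np.asarray(self.covariate_mean, dtype=float).reshape(-1)
        self.covariate_covariance = np.asarray(self.covariate_covariance, dtype=float)
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.covariate_mean.size != 12:
            raise ValueError("covariate_mean must have 12 entries (V5..V60)")
        if self.covariate_covariance.shape != (12, 12):
            raise ValueError("covariate_covariance must be 12x12")
        if not np.allclose(self.covariate_covariance, self.covariate_covariance.T):
            raise ValueError("covariate_covariance must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.covariate_covariance).min())
        if eigmin < -1e-8 * max(1.0, np.abs(self.covariate_covariance).max()):
            raise ValueError(
                f"covariate_covariance is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})"
            )


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a cohort table of correlated Vx covariates and RP outcomes.

    Covariates are drawn from N(mean, cov), clipped to [0, 100] and sorted in
    descending order within each row so every patient's V5 ≥ V10 ≥ … ≥ V60,
    i.e. each row is a valid cumulative dose-volume vector. The grade-≥2
    pneumonitis indicator is Bernoulli with probability
    sigmoid(true_model linear predictor) on the final covariates.
    """
    rng = np.random.default_rng(spec.seed)
    v = rng.multivariate_normal(
        spec.covariate_mean, spec.covariate_covariance, size=spec.n_patients,
        method="cholesky" if _is_pd(spec.covariate_covariance) else "eigh",
    )
    v = np.clip(v, 0.0, 100.0)
    v = np.sort(v, axis=1)[:, ::-1]  # enforce V5 >= V10 >= ... >= V60

    lp = np.full(spec.n_patients, spec.true_model.intercept)
    for name, beta in spec.true_model.coefficients.items():
        lp = lp + beta * v[:, FV_COLUMNS.index(name)]
    outcome = rng.binomial(1, expit(lp))

    table = pd.DataFrame(v, columns=FV_COLUMNS)
    table.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(spec.n_patients)])
    table[OUTCOME_COLUMN] = outcome
    return table


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False
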