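"""End-to-end pipeline: phantom → registration → ventilation → functional
DVH → cohort simulation → model selection → evaluation.

A single validated config (YAML or an in-memory :class:`PipelineConfig`)
drives every stage with explicit seeds; all intermediate artifacts are
written to the output directory as uncompressed NIfTI / CSV / JSON, and a
manifest records a SHA-256 hash of each file plus the headline statistics,
so a rerun with the same config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path
from typing import List, Literal, Optional, Tuple, Union

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import dvf as dvf_mod
from . import io as io_mod
from .dvh import extract_fv_vector
from .evaluation import calibrate_bootstrap, nomogram_points, roc_auc
from .grids import DisplacementField, ImageGrid
from .phantom import (
    DEFAULT_SEED,
    CohortSimSpec,
    PhantomSpec,
    generate_dose_grid,
    generate_phantom_pair,
    simulate_cohort,
)
from .riskmodel import (
    SelectionResult,
    best_subset_select,
    ensemble_importance,
    fit_logistic,
    lasso_select,
    stepwise_select,
)
from .ventilation import jacobian_determinant, segment_high_function

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class PhantomStage(BaseModel):
    grid_shape: Tuple[int, int, int] = (32, 32, 32)
    spacing: Tuple[float, float, float] = (5.0, 5.0, 5.0)
    motion_amplitude: float = Field(15.0, ge=0)
    motion_decay: float = 2.0
    noise_sd: float = Field(10.0, ge=0)
    seed: int = DEFAULT_SEED

    @field_validator("grid_shape")
    @classmethod
    def _min_shape(cls, v):
        if any(n < 8 for n in v):
            raise ValueError("grid_shape entries must be >= 8")
        return v


class RegistrationStage(BaseModel):
    levels: int = Field(3, ge=1)
    iterations_per_level: int = Field(30, ge=1)
    smoothing_sigma_mm: float = Field(2.0, gt=0)
    use_truth_field: bool = False


class VentilationStage(BaseModel):
    threshold: float = 1.2
    presmooth_sigma_mm: Optional[float] = None


class DoseStage(BaseModel):
    prescription: float = Field(60.0, gt=0)
    falloff_mm: float = Field(40.0, gt=0)
    target_center_mm: Optional[Tuple[float, float, float]] = None


class CohortStage(BaseModel):
    n_patients: int = Field(41, ge=2)
    seed: int = DEFAULT_SEED


class ModelStage(BaseModel):
    method: Literal["stepwise", "best_subset", "lasso", "forest"] = "stepwise"
    candidates: List[str] = Field(default_factory=lambda: list(io_mod.FV_COLUMNS))
    seed: int = DEFAULT_SEED


class EvaluationStage(BaseModel):
    n_boot: int = Field(200, ge=0)
    seed: int = DEFAULT_SEED
    alpha: float = Field(0.05, gt=0, lt=1)


class PipelineConfig(BaseModel):
    """Validated configuration of the full pipeline (one block per stage)."""

    output_dir: str
    phantom: PhantomStage = PhantomStage()
    registration: RegistrationStage = RegistrationStage()
    ventilation: VentilationStage = VentilationStage()
    dose: DoseStage = DoseStage()
    cohort: CohortStage = CohortStage()
    model: ModelStage = ModelStage()
    evaluation: EvaluationStage = EvaluationStage()


def load_config(path: Union[str, os.PathLike]) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _select(table, cfg: ModelStage) -> SelectionResult:
    if cfg.method == "stepwise":
        return stepwise_select(table, cfg.candidates)
    if cfg.method == "best_subset":
        return best_subset_select(table, cfg.candidates)
    if cfg.method == "lasso":
        return lasso_select(table, cfg.candidates, seed=cfg.seed)
    return ensemble_importance(table, cfg.candidates, seed=cfg.seed)


def run_pipeline(config: Union[PipelineConfig, dict, str, os.PathLike]) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    if isinstance(config, (str, os.PathLike)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = PipelineConfig(**config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats: dict = {}

    # --- phantom -----------------------------------------------------------
    spec = PhantomSpec(
        grid_shape=config.phantom.grid_shape,
        spacing=config.phantom.spacing,
        motion_amplitude=config.phantom.motion_amplitude,
        motion_decay=config.phantom.motion_decay,
        noise_sd=config.phantom.noise_sd,
        seed=config.phantom.seed,
    )
    exhale, inhale, truth, lung = generate_phantom_pair(spec)
    io_mod.write_image(exhale, str(out / "exhale.nii"))
    io_mod.write_image(inhale, str(out / "inhale.nii"))
    io_mod.write_displacement_field(truth, str(out / "truth_dvf.nii"))
    io_mod.write_mask(lung, str(out / "lung.nii"))
    stats["lung_volume_cc"] = lung.volume_cc

    # --- registration ------------------------------------------------------
    if config.registration.use_truth_field:
        field: DisplacementField = truth
    else:
        field = dvf_mod.register_demons(
            inhale,
            exhale,
            levels=config.registration.levels,
            iterations_per_level=config.registration.iterations_per_level,
            smoothing_sigma_mm=config.registration.smoothing_sigma_mm,
        )
        stats["registration_mse_before"] = dvf_mod.mse(inhale, exhale)
        stats["registration_mse_after"] = dvf_mod.mse(
            inhale, dvf_mod.warp_image(exhale, field)
        )
    io_mod.write_displacement_field(field, str(out / "dvf.nii"))

    # --- ventilation -------------------------------------------------------
    vent = jacobian_determinant(field)
    flung = segment_high_function(
        vent,
        lung,
        threshold=config.ventilation.threshold,
        presmooth_sigma_mm=config.ventilation.presmooth_sigma_mm,
    )
    io_mod.write_image(
        ImageGrid(values=vent.jacobian, spacing=vent.spacing, origin=vent.origin),
        str(out / "jacobian.nii"),
    )
    io_mod.write_mask(flung, str(out / "flung.nii"))
    stats["flung_volume_cc"] = flung.volume_cc

    # --- dose and functional DVH ------------------------------------------
    target = config.dose.target_center_mm or tuple(spec.lung_geometry[0].center)
    dose = generate_dose_grid(
        spec, target, config.dose.prescription, config.dose.falloff_mm
    )
    io_mod.write_dose(dose, str(out / "dose.nii"))
    if flung.voxel_count > 0:
        fv = extract_fv_vector(dose, flung)
        fv.as_series().to_frame().T.to_csv(out / "fv.csv", index=False)
        stats["fv_vector"] = {k: float(v) for k, v in fv.as_series().items()}
    else:
        logger.warning("fLung is empty at threshold %s; no functional DVH",
                       config.ventilation.threshold)
        stats["fv_vector"] = None

    # --- cohort, selection, evaluation -------------------------------------
    cohort = simulate_cohort(
        CohortSimSpec(n_patients=config.cohort.n_patients, seed=config.cohort.seed)
    )
    io_mod.write_cohort(cohort, out / "cohort.csv")
    stats["cohort_prevalence"] = float(cohort[io_mod.OUTCOME_COLUMN].mean())

    selection = _select(cohort, config.model)
    stats["selection_method"] = selection.method
    stats["selected"] = selection.selected
    sel_payload = {"method": selection.method, "selected": selection.selected}
    if selection.importances is not None:
        sel_payload["importances"] = selection.importances
    (out / "selection.json").write_text(json.dumps(sel_payload, indent=2, sort_keys=True))

    report: dict = {"selection": sel_payload}
    if selection.final_model is not None:
        model = selection.final_model
        (out / "model.json").write_text(
            model.to_json(method=selection.method, selected=selection.selected)
        )
        scores = model.predict_probability(cohort)
        roc = roc_auc(scores, cohort[io_mod.OUTCOME_COLUMN].to_numpy(),
                      alpha=config.evaluation.alpha)
        stats["auc"] = roc.auc
        report["roc"] = {
            "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "alpha": roc.alpha,
        }
        cal = calibrate_bootstrap(
            cohort, selection.selected, n_boot=config.evaluation.n_boot,
            seed=config.evaluation.seed,
        )
        report["calibration"] = {
            "slope": cal.slope, "intercept": cal.intercept, "n_boot": cal.n_boot,
            "grid": cal.grid.tolist(), "apparent": cal.apparent.tolist(),
            "bias_corrected": None if cal.bias_corrected is None
            else cal.bias_corrected.tolist(),
        }
        if selection.selected:
            ranges = {
                c: (float(cohort[c].min()), float(cohort[c].max()))
                for c in selection.selected
            }
            ranges = {c: r for c, r in ranges.items() if r[1] > r[0]}
            if set(ranges) == set(selection.selected):
                nomo = nomogram_points(model, ranges)
                report["nomogram"] = {
                    "variables": nomo.variables,
                    "max_points_variable": nomo.max_points_variable,
                    "denom": nomo.denom,
                }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    files = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "stats": stats,
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
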