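"""End-to-end driver: simulate -> PPI -> classify -> evaluate.

``run_pipeline`` executes the whole chain reproducibly from one
:class:`~ppimlda.config.PipelineConfig` and writes every artifact a reader
needs to audit the run: the cohort table, per-subject decision values, the
metrics report (with the config hash and the explicit analysis decisions —
shrinkage rule, ranking rule, fold-nested selection), the ROC polyline and
the back-projected discriminant weight map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import PipelineConfig
from .metrics import MetricsReport, evaluate_cv
from .mlda import CVResult, fit_pipeline, loocv, export_weight_map
from .ppi import (
    GUILT_VS_INDIGNATION,
    HRFSpec,
    PPIMap,
    assemble_ppi_design,
    build_psych_regressor,
    extract_seed_timeseries,
    feature_matrix,
    fit_glm_tmap,
)
from .synthetic import (
    SyntheticCohort,
    default_event_schedules,
    generate_ppi_maps,
    generate_timeseries_cohort,
    make_gray_matter_map,
)
from .volume import VolumeGrid

log = logging.getLogger("ppimlda")


@dataclass
class PipelineReport:
    metrics: MetricsReport
    cv_result: CVResult
    weight_map: VolumeGrid
    cohort: SyntheticCohort
    artifacts: dict[str, Path]


def simulate_cohort(config: PipelineConfig) -> tuple[SyntheticCohort, VolumeGrid]:
    """Synthetic cohort plus the gray-matter map it was drawn under."""
    grid = config.sim.make_grid()
    gm = make_gray_matter_map(grid, rng_seed=config.sim.rng_seed + 1)
    mask = gm.data > config.gm_threshold
    if config.mode == "maps":
        cohort = generate_ppi_maps(config.sim, mask)
    else:
        rng = np.random.default_rng(config.sim.rng_seed + 2)
        events = default_event_schedules(config.sim, rng)
        cohort = generate_timeseries_cohort(config.sim, mask, events)
    return cohort, gm


def ppi_maps_for_cohort(cohort: SyntheticCohort, config: PipelineConfig) -> list[PPIMap]:
    """Subject-level contrast t-maps.

    In "maps" mode the simulated volumes already stand for interaction maps
    and are passed through; in "timeseries" mode each subject's runs are
    concatenated, the seed series is extracted from the ROI, and the PPI GLM
    is fit with per-run intercepts.
    """
    if config.mode == "maps":
        return [
            PPIMap(t_values=m, dof=0, contrast_name="synthetic")
            for m in cohort.maps
        ]
    sim = cohort.config
    hrf = HRFSpec()
    psych_runs = [
        build_psych_regressor(ev, GUILT_VS_INDIGNATION, hrf, sim.n_volumes, sim.tr_s)
        for ev in cohort.events
    ]
    maps = []
    for runs in cohort.maps:
        seed_ts = np.concatenate(
            [extract_seed_timeseries(r, cohort.seed_roi) for r in runs]
        )
        psych = np.concatenate(psych_runs)
        design = assemble_ppi_design(
            seed_ts, psych, run_lengths=[sim.n_volumes] * sim.n_runs
        )
        concat = runs[0].with_data(
            np.concatenate([r.data for r in runs], axis=3)
        )
        maps.append(
            fit_glm_tmap(
                concat,
                design,
                design.contrast_vector(config.contrast),
                contrast_name=config.contrast,
            )
        )
    return maps


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineReport:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: mode=%s contrast=%s hash=%s",
             config.mode, config.contrast, config.config_hash())

    cohort, gm = simulate_cohort(config)
    maps = ppi_maps_for_cohort(cohort, config)
    X, index = feature_matrix(maps, gm, config.gm_threshold)
    log.info("feature matrix: %d subjects x %d voxels", *X.shape)

    cv = loocv(
        X,
        cohort.labels,
        fraction=config.fraction,
        ranking=config.ranking,
        lambda_bar_rule=config.lambda_bar_rule,
        subject_ids=cohort.subject_ids(),
    )
    metrics = evaluate_cv(cv)
    metrics.metadata.update(
        {
            "config_hash": config.config_hash(),
            "contrast": config.contrast,
            "selection_fraction": config.fraction,
            "ranking_rule": config.ranking,
            "lambda_bar_rule": config.lambda_bar_rule,
            "feature_selection_nested_in_folds": True,
        }
    )

    full_model = fit_pipeline(
        X, cohort.labels, config.fraction, config.ranking, config.lambda_bar_rule
    )
    wmap = export_weight_map(full_model, index)

    artifacts: dict[str, Path] = {}
    artifacts["config"] = config.to_yaml(out / "config_used.yaml")
    artifacts["cohort_table"] = pio.write_cohort_table(
        cohort.subject_ids(), cohort.labels, out / "participants.tsv"
    )
    cv_path = out / "cv_results.tsv"
    cv.to_frame().to_csv(cv_path, sep="\t", index=False, float_format="%.12g")
    artifacts["cv_results"] = cv_path
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(metrics.to_dict(), indent=2))
    artifacts["metrics"] = metrics_path
    roc_path = out / "roc_points.tsv"
    pd.DataFrame(metrics.roc_points, columns=["fpr", "tpr"]).to_csv(
        roc_path, sep="\t", index=False
    )
    artifacts["roc_points"] = roc_path
    artifacts["weight_map"] = pio.write_nifti(wmap, out / "weight_map.nii.gz")
    artifacts["gray_matter"] = pio.write_nifti(gm, out / "gray_matter.nii.gz")
    artifacts["truth_mask"] = pio.write_nifti(
        gm.with_data(cohort.truth_mask.astype(float)), out / "truth_mask.nii.gz"
    )
    log.info(
        "pipeline done: accuracy=%.4f auc=%s", metrics.accuracy,
        f"{metrics.auc:.4f}" if metrics.auc is not None else "n/a",
    )
    return PipelineReport(metrics, cv, wmap, cohort, artifacts)
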