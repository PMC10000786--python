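"""End-to-end orchestration: generator -> preprocessing/ROI -> features ->
classification -> group statistics, with manifests and file outputs.

A run directory contains a ``manifest.json`` (config hash, seed, package
version, per-stage outputs), the cohort and feature tables as CSV, the
selection audit and final-evaluation report as JSON, and ROC coordinates
as CSV. Reruns with the same config are byte-identical (no timestamps in
any artifact).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    EvalProtocol,
    SelectionError,
    enumerate_eligible_pairs,
    final_evaluation,
    select_congenic_pair,
    select_final_features,
)
from .datatypes import InvalidArgumentError
from .features import FeatureConfig, SmoothingConfig, cohort_feature_table
from .group_stats import compare_strain_curves
from .preprocessing import subtract_background
from .roi import detect_tumor_roi, extract_series
from .synthetic import (
    augment_records,
    default_cohort_spec,
    default_phantom_layout,
    make_reference_images,
    render_stack,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (desk-scale defaults)."""

    seed: int = 0
    output_dir: str = "stratify_run"
    # stage toggles
    run_phantom_check: bool = True
    run_classification: bool = True
    run_group_stats: bool = True
    run_augmented: bool = False
    # generator
    n_frames: int = 3000
    fps: float = 10.6
    effect_scale: float = 1.0
    # phantom validation stage
    n_phantoms: int = 2
    phantom_shape: tuple = (64, 64)
    phantom_frames: int = 600
    # evaluation protocol
    test_fraction: float = 0.25
    n_repeats: int = 5
    inner_cv_folds: int = 5
    # augmentation
    n_augmented: int = 606
    # group stats
    stats_timepoints: int = 1400

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "phantom_shape" in raw:
            raw["phantom_shape"] = tuple(raw["phantom_shape"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }

    # --- synthetic cohort -------------------------------------------------
    spec = default_cohort_spec(
        seed=config.seed,
        effect_scale=config.effect_scale,
        n_frames=config.n_frames,
        fps=config.fps,
    )
    from .synthetic import generate_cohort

    records = generate_cohort(spec)
    cohort_df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "dll4_label": [r.dll4_label for r in records],
            "n_fatpads": [r.n_fatpads for r in records],
        }
    )
    cohort_path = out / "cohort.csv"
    cohort_df.to_csv(cohort_path, index=False)
    manifest["stages"]["synthetic"] = {
        "n_records": len(records),
        "cohort_csv": cohort_path.name,
    }

    # --- phantom imaging check (preprocessing + ROI detection) ------------
    if config.run_phantom_check:
        rows, cols = config.phantom_shape
        refs = make_reference_images(shape=(rows, cols), n=4, seed=config.seed + 7)
        dices, cent_errs = [], []
        for i in range(config.n_phantoms):
            rec = records[i]
            layout = default_phantom_layout(
                rows, cols, n_fatpads=rec.n_fatpads, seed=config.seed + 100 + i
            )
            short = dataclasses.replace(rec)
            n_curve = config.phantom_frames - 50
            short.tumor = _truncate(rec.tumor, n_curve)
            short.fatpads = [_truncate(fp, n_curve) for fp in rec.fatpads]
            stack = render_stack(
                short,
                layout,
                rows,
                cols,
                n_background_frames=50,
                pixel_noise_sd=0.01,
                seed=config.seed + 200 + i,
            )
            corrected = subtract_background(stack)
            rois, _ranking = detect_tumor_roi(corrected, refs)
            true_mask = layout.tumor.mask(rows, cols)
            inter = np.logical_and(rois.tumor_mask, true_mask).sum()
            dice = 2 * inter / (rois.tumor_mask.sum() + true_mask.sum())
            cent_err = float(
                np.hypot(
                    rois.tumor_centroid[0] - layout.tumor.center_row,
                    rois.tumor_centroid[1] - layout.tumor.center_col,
                )
            )
            dices.append(float(dice))
            cent_errs.append(cent_err)
            # sanity: extraction works on detected masks
            extract_series(corrected, rois)
        manifest["stages"]["phantom_check"] = {
            "n_phantoms": config.n_phantoms,
            "dice": dices,
            "centroid_error_px": cent_errs,
        }

    # --- features ---------------------------------------------------------
    fcfg = FeatureConfig(fps=config.fps)
    table = cohort_feature_table(records, SmoothingConfig(), fcfg)
    features_path = out / "features.csv"
    table.to_csv(features_path, index=False, float_format="%.10g")
    manifest["stages"]["features"] = {
        "n_rows": int(len(table)),
        "n_feature_columns": int(len(table.columns) - 3),
        "features_csv": features_path.name,
    }

    # --- classification ---------------------------------------------------
    if config.run_classification:
        protocol = EvalProtocol(
            test_fraction=config.test_fraction,
            n_repeats=config.n_repeats,
            inner_cv_folds=config.inner_cv_folds,
            base_seed=config.seed,
        )
        pairs = enumerate_eligible_pairs(cohort_df)
        audit = {"eligible_pairs": [list(p) for p in pairs]}
        try:
            sel = select_congenic_pair(table, cohort_df, protocol=protocol)
            audit["stage1"] = sel.stage1.to_dict(orient="records")
            audit["stage2"] = _jsonable_stage2(sel.stage2)
            audit["selected_pair"] = list(sel.selected_pair)
            audit["selected_features"] = list(sel.selected_features)
            # final feature pair refined on parental + selected congenic groups
            selected_features, _ = select_final_features(
                table, sel.selected_pair, protocol=protocol
            )
            audit["final_features"] = list(selected_features)
            excluded = {"Dll4+", "Dll4-", *sel.selected_pair}
        except SelectionError as exc:
            audit["selection_failure"] = str(exc)
            selected_features = None
            excluded = None
        with open(out / "selection_audit.json", "w") as fh:
            json.dump(audit, fh, indent=2, sort_keys=True)
        manifest["stages"]["selection"] = {"audit_json": "selection_audit.json"}

        if selected_features is not None:
            train_groups = sorted(set(cohort_df["group"]) - excluded)
            results = final_evaluation(
                table,
                train_groups,
                selected_features,
                models=("linear_svm", "knn"),
                protocol=protocol,
                report_path=out / "final_report.json",
                roc_path=out / "final_roc.csv",
            )
            manifest["stages"]["final"] = {
                "train_groups": train_groups,
                "selected_features": list(selected_features),
                "auc": {name: res.auc for name, res in results.items()},
                "report_json": "final_report.json",
                "roc_csv": "final_roc.csv",
            }
            if config.run_augmented:
                base = [r for r in records if r.group in train_groups]
                aug = augment_records(base, config.n_augmented, seed=config.seed)
                aug_table = cohort_feature_table(aug, SmoothingConfig(), fcfg)
                aug_protocol = EvalProtocol(
                    test_fraction=0.20,
                    n_repeats=config.n_repeats,
                    inner_cv_folds=config.inner_cv_folds,
                    base_seed=config.seed,
                )
                aug_results = final_evaluation(
                    aug_table,
                    train_groups,
                    selected_features,
                    models=("linear_svm", "knn"),
                    protocol=aug_protocol,
                    report_path=out / "final_report_augmented.json",
                    roc_path=out / "final_roc_augmented.csv",
                )
                manifest["stages"]["final_augmented"] = {
                    "n_records": len(aug),
                    "auc": {name: res.auc for name, res in aug_results.items()},
                    "report_json": "final_report_augmented.json",
                }

    # --- group statistics -------------------------------------------------
    if config.run_group_stats:
        res, pmat = compare_strain_curves(records, n_timepoints=config.stats_timepoints)
        pmat.to_csv(out / "tukey_pvalues.csv", float_format="%.6g")
        pd.DataFrame(
            {"time_s": res.timepoints, "diag_covariance": res.diag_projection}
        ).to_csv(out / "covariance_diag.csv", index=False, float_format="%.10g")
        manifest["stages"]["group_stats"] = {
            "n_timepoints": int(res.timepoints.size),
            "df_error": res.df_error,
            "pvalues_csv": "tukey_pvalues.csv",
            "covariance_diag_csv": "covariance_diag.csv",
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _truncate(series, n):
    from .datatypes import IntensitySeries

    return IntensitySeries(series.values[:n], series.fps, name=series.name)


def _jsonable_stage2(stage2: pd.DataFrame) -> list:
    rows = stage2.copy()
    rows["features"] = rows["features"].apply(list)
    return rows.to_dict(orient="records")
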