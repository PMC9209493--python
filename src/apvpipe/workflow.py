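"""Pipeline orchestration: batch extraction and train/evaluate runs.

These functions are the library layer behind the command-line interface:
they read manifests and tables, run the extraction and the two-stage fit,
and write deterministic artefacts (feature CSVs, model JSON, report CSVs,
run manifest) into an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import (
    STAGE1_CONTRAST,
    STAGE2_CONTRAST,
    EmptyModelError,
    StageConfig,
    fit_cascade,
    fit_stage,
    train_validation_split,
)
from .diagnostics import roc_curve
from .image_io import RegionTable, read_labelmap, read_volume, resample_isotropic
from .phantom import PhantomSpec, SyntheticCohort, make_cohort, phantom_region_table, study_spec
from .radiomics import FeatureCatalogue, default_catalogue, extract_subject_features
from .screening import FeatureMatrix

logger = logging.getLogger("apvpipe")


class UsageError(ValueError):
    pass


class StratificationError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    region_set: str = "ALL115"            # WM45 | ALL115
    catalogue: FeatureCatalogue | None = None
    screening_test: str = "mann_whitney"
    fdr_level: float = 0.05
    family: str = "binomial"
    folds: int = 10
    seed: int = 0
    include_scores: bool = False
    split_fraction: float = 0.7
    target_spacing: float = 1.0
    min_voxels: int = 27

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must lie in (0, 1)")
        if self.region_set not in ("WM45", "ALL115"):
            raise ValueError(f"unknown region set {self.region_set!r}")
        if self.catalogue is None:
            self.catalogue = default_catalogue()

    def stage_config(self) -> StageConfig:
        return StageConfig(
            screening_test=self.screening_test,
            fdr_level=self.fdr_level,
            family=self.family,
            folds=self.folds,
            seed=self.seed,
        )


def run_extract(
    config: RunConfig,
    manifest: pd.DataFrame,
    regions: RegionTable | None = None,
    out_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Extract one feature row per manifest subject.

    Manifest columns: subject_id, volume, labelmap.  Per-subject failures
    are logged and skipped; the run continues and the failed ids are
    returned so a caller (e.g. the CLI) can signal a nonzero exit.
    """
    if manifest.empty:
        raise UsageError("empty subject manifest")
    required = {"subject_id", "volume", "labelmap"}
    if not required <= set(manifest.columns):
        raise UsageError(f"manifest must have columns {sorted(required)}")
    regions = regions or RegionTable.default()
    rows: dict[str, pd.Series] = {}
    failures: list[str] = []
    for _, rec in manifest.iterrows():
        sid = str(rec["subject_id"])
        try:
            vol = read_volume(rec["volume"])
            lmap = read_labelmap(rec["labelmap"], regions)
            vol, lmap = resample_isotropic(vol, lmap, target=config.target_spacing)
            rows[sid] = extract_subject_features(
                vol, lmap, regions, config.catalogue,
                region_set=config.region_set, min_voxels=config.min_voxels,
            )
        except Exception as exc:
            logger.error("subject %s failed: %s", sid, exc)
            failures.append(sid)
    if not rows:
        raise UsageError("every subject failed feature extraction")
    table = pd.DataFrame(rows).T.rename_axis("subject_id")
    if out_csv is not None:
        table.to_csv(out_csv)
    return table, failures


def cohort_feature_matrix(
    cohort: SyntheticCohort,
    regions: RegionTable,
    catalogue: FeatureCatalogue | None = None,
    region_set: str = "WM45",
    min_voxels: int = 27,
) -> FeatureMatrix:
    """Extract features for every phantom subject into a FeatureMatrix."""
    catalogue = catalogue or default_catalogue()
    rows = {
        s.subject_id: extract_subject_features(
            s.volume, s.labelmap, regions, catalogue,
            region_set=region_set, min_voxels=min_voxels,
        )
        for s in cohort.subjects
    }
    data = pd.DataFrame(rows).T.rename_axis("subject_id")
    return FeatureMatrix(data=data, groups=cohort.groups())


def feature_region_name(column: str) -> str:
    """The region part of a ``region__channel__family__name`` column."""
    return column.split("__")[0]


def phantom_recovery_run(
    seed: int,
    spec: PhantomSpec | None = None,
    n_per_group: int = 60,
    catalogue: FeatureCatalogue | None = None,
    split_fraction: float = 0.7,
) -> dict:
    """One end-to-end parameter-recovery experiment on a phantom cohort.

    Generates the cohort, extracts features, fits stage 1 on the 70% train
    split, and reports the held-out ROC AUC plus the precision with which
    the selected features fall inside the planted signal regions.  A screen
    that keeps nothing (possible on signal-free cohorts) yields an
    intercept-only model whose constant scores give AUC 0.5 under the tie
    convention.
    """
    spec = spec or study_spec()
    catalogue = catalogue or default_catalogue(channels=("original",))
    cohort = make_cohort(spec, n_per_group=n_per_group, seed=seed)
    table = phantom_region_table(spec.n_regions)
    fm = cohort_feature_matrix(cohort, table, catalogue)
    train, val = train_validation_split(fm, fraction=split_fraction, seed=seed)
    y_val = val.binary_labels(set(STAGE1_CONTRAST[0]), set(STAGE1_CONTRAST[1])).to_numpy()
    try:
        model = fit_stage(train, STAGE1_CONTRAST, config=StageConfig(seed=seed))
    except EmptyModelError:
        return {"auc": 0.5, "precision": float("nan"), "n_selected": 0, "model": None}
    scores = model.score(val).to_numpy()
    auc = roc_curve(scores, y_val).auc
    signal_names = {
        table.name_of(rid) for rid in spec.signal_regions()
    } if spec.signal_regions() else set()
    selected_regions = [feature_region_name(c) for c in model.selected]
    precision = (
        float(np.mean([r in signal_names for r in selected_regions]))
        if selected_regions and signal_names
        else float("nan")
    )
    return {
        "auc": float(auc),
        "precision": precision,
        "n_selected": int(len(model.selected)),
        "model": model,
        "validation": val,
        "y_val": y_val,
    }


def run_train_eval(
    config: RunConfig,
    features: pd.DataFrame,
    groups: pd.Series,
    scores: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Stratified 70/30 split, two-stage fit on the training split, and
    diagnostic reports per stage on both splits.

    Returns a dict with the fitted model, the split, and the four reports;
    writes model JSON, report CSVs and a reproducibility manifest when an
    output directory is given.
    """
    missing = groups.index.symmetric_difference(features.index)
    if groups.reindex(features.index).isna().any():
        raise UsageError(f"labels do not cover all subjects: {list(missing)[:5]}")
    m = FeatureMatrix(data=features, groups=groups.reindex(features.index), scores=scores)
    train, val = train_validation_split(m, fraction=config.split_fraction, seed=config.seed)
    for split_name, part in (("train", train), ("validation", val)):
        present = set(part.groups.unique())
        if not present & set(STAGE2_CONTRAST[0]) or not present & set(STAGE2_CONTRAST[1]):
            raise StratificationError(f"a contrast class is missing from the {split_name} split")

    model = fit_cascade(
        train,
        include_scores=config.include_scores,
        config=config.stage_config(),
        region_set=config.region_set,
        catalogue_hash=config.catalogue.content_hash(),
    )

    reports = {}
    for split_name, part in (("train", train), ("validation", val)):
        for stage_name, stage, contrast in (
            ("stage1", model.stage1, STAGE1_CONTRAST),
            ("stage2", model.stage2, STAGE2_CONTRAST),
        ):
            labels = part.binary_labels(set(contrast[0]), set(contrast[1]))
            sub = part.select_subjects(labels.index)
            reports[f"{split_name}_{stage_name}"] = stage.evaluate(sub, labels)
    predictions = model.predict(val)

    result = {
        "model": model,
        "train": train,
        "validation": val,
        "reports": reports,
        "predictions": predictions,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.to_json(out / "cascade_model.json")
        for name, report in reports.items():
            report.to_csv(out / f"report_{name}.csv")
        predictions.rename_axis("subject_id").to_csv(out / "predictions.csv")
        manifest = {
            "seed": config.seed,
            "region_set": config.region_set,
            "family": config.family,
            "folds": config.folds,
            "include_scores": config.include_scores,
            "split_fraction": config.split_fraction,
            "catalogue_hash": config.catalogue.content_hash(),
            "n_subjects": int(len(features)),
            "n_features": int(features.shape[1]),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
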