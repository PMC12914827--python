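"""End-to-end orchestration: harmonize -> ensemble -> stratify -> validate
-> (optional) simplify, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    calls_to_frame,
    evaluate_classifier,
    predict_subgroup,
    split_train_validation,
    train_ensemble,
)
from .harmonize import zscore_normalize
from .io import (
    read_clinical_csv,
    read_expression_tsv,
    write_clinical_csv,
    write_expression_tsv,
)
from .selection import simplify_signature
from .survival import treatment_effect_by_subgroup
from .synthetic import (
    CellLinePanel,
    CohortSpec,
    PanelSpec,
    PatientCohort,
    generate_cellline_panel,
    generate_patient_cohort,
)


@dataclass
class PipelineConfig:
    # generator specs (used when the corresponding file paths are None)
    panel_spec: PanelSpec = field(default_factory=PanelSpec)
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    panel_tsv: str | None = None
    panel_labels_csv: str | None = None
    cohort_tsv: str | None = None
    clinical_csv: str | None = None
    # ensemble
    n_members: int = 500
    n_estimators: int = 100
    vote_threshold: float = 0.6
    split_ratio: float = 0.8
    # selection
    run_simplification: bool = False
    max_k: int | None = None
    stability_window: int = 0
    # analysis
    treatment_col: str = "chemo"
    alpha: float = 0.05
    # bookkeeping
    seed: int = 0
    outdir: str = "kinsig_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_panel(config: PipelineConfig) -> CellLinePanel:
    if config.panel_tsv is None:
        spec = dataclasses.replace(config.panel_spec, seed=config.panel_spec.seed or config.seed)
        return generate_cellline_panel(spec)
    matrix = read_expression_tsv(config.panel_tsv, cohort="cellline_panel")
    labels_df = pd.read_csv(config.panel_labels_csv, index_col="sample_id")
    if "subgroup" not in labels_df.columns:
        raise ValueError("panel labels file lacks column: subgroup")
    return CellLinePanel(
        matrix=matrix,
        labels=labels_df["subgroup"],
        line_ids=labels_df.get("line_id", pd.Series(labels_df.index, index=labels_df.index)),
        informative_features=(),
    )


def _load_cohort(config: PipelineConfig) -> PatientCohort:
    if config.cohort_tsv is None:
        spec = dataclasses.replace(config.cohort_spec, seed=config.cohort_spec.seed or config.seed)
        return generate_patient_cohort(spec)
    matrix = read_expression_tsv(config.cohort_tsv)
    clinical = read_clinical_csv(config.clinical_csv)
    latent = clinical.get("latent_subgroup", pd.Series(index=clinical.index, dtype=object))
    return PatientCohort(matrix=matrix, clinical=clinical, latent_subgroup=latent)


@dataclass
class PipelineResult:
    outdir: Path
    criteria: object
    validation_metrics: object
    trace: object | None
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write its artifact bundle.

    Raises with stage-named diagnostics; reruns with an identical config
    are deterministic.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    panel = _load_panel(config)
    cohort = _load_cohort(config)
    if config.treatment_col not in cohort.clinical.columns:
        raise ValueError(
            f"[stratify] cohort clinical table lacks treatment column "
            f"'{config.treatment_col}'"
        )

    write_expression_tsv(panel.matrix, out / "panel.tsv")
    pd.DataFrame({"subgroup": panel.labels, "line_id": panel.line_ids}).rename_axis(
        "sample_id"
    ).to_csv(out / "panel_labels.csv")
    write_expression_tsv(cohort.matrix, out / "cohort.tsv")
    write_clinical_csv(cohort.clinical, out / "clinical.csv")

    # harmonize
    panel_norm = CellLinePanel(
        matrix=zscore_normalize(panel.matrix),
        labels=panel.labels,
        line_ids=panel.line_ids,
        informative_features=panel.informative_features,
        spec=panel.spec,
    )
    cohort_norm = zscore_normalize(cohort.matrix)

    # ensemble
    train, val = split_train_validation(panel_norm, ratio=config.split_ratio, seed=config.seed)
    model = train_ensemble(
        train,
        n_members=config.n_members,
        n_estimators=config.n_estimators,
        seed=config.seed,
        vote_threshold=config.vote_threshold,
    )
    val_calls = predict_subgroup(model, val.matrix)
    metrics = evaluate_classifier(val_calls, val.labels)
    model.importance.rename_axis("feature").to_csv(out / "importance.csv")
    with open(out / "model.pkl", "wb") as fh:
        pickle.dump(
            {
                "members": model.members,
                "member_seeds": model.member_seeds,
                "feature_names": model.feature_names,
                "vote_threshold": model.vote_threshold,
                "importance": model.importance,
                "metadata": model.metadata,
            },
            fh,
        )

    # stratify + validate
    calls = predict_subgroup(model, cohort_norm)
    calls_to_frame(calls).to_csv(out / "subgroup_calls.csv")
    criteria, fits = treatment_effect_by_subgroup(
        cohort.clinical, calls, config.treatment_col, alpha=config.alpha
    )
    for grp, fit in fits.items():
        if fit is not None:
            fit.summary.to_csv(out / f"cox_treatment_{grp}.csv")

    trace = None
    if config.run_simplification:
        trace = simplify_signature(
            panel,  # selection normalises internally
            cohort,
            treatment_col=config.treatment_col,
            max_k=config.max_k,
            base_seed=config.seed,
            n_members=config.n_members,
            n_estimators=config.n_estimators,
            stability_window=config.stability_window,
        )
        trace.records.to_csv(out / "selection_trace.csv")
        (out / "chosen_panel.txt").write_text("\n".join(trace.chosen_features) + "\n")

    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "validation_metrics": {
            "accuracy": metrics.accuracy,
            "f1": metrics.f1,
            "auc": metrics.auc,
        },
        "criteria": {
            "hr_emt": criteria.hr_emt,
            "p_emt": criteria.p_emt,
            "hr_met": criteria.hr_met,
            "p_met": criteria.p_met,
            "passed": criteria.passed,
            "reasons": criteria.reasons,
        },
        "selection": None
        if trace is None
        else {
            "status": trace.status,
            "chosen_k": trace.chosen_k,
            "chosen_features": trace.chosen_features,
            "cumulative_importance": trace.cumulative_importance,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(
        outdir=out,
        criteria=criteria,
        validation_metrics=metrics,
        trace=trace,
        manifest=manifest,
    )
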