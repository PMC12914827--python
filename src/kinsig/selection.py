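"""Survival-criteria-driven forward simplification of the signature.

Features are ranked once by averaged ensemble importance from a
full-feature ensemble, then added one at a time; at each panel size the
ensemble is retrained on the top-k features, the patient cohort is
stratified, and the per-subgroup treatment-benefit criteria are
evaluated. The chosen panel is the smallest k whose criteria pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import (
    evaluate_classifier,
    predict_subgroup,
    split_train_validation,
    train_ensemble,
)
from .harmonize import select_features, zscore_normalize
from .survival import treatment_effect_by_subgroup
from .synthetic import CellLinePanel, PatientCohort


@dataclass
class SelectionTrace:
    records: pd.DataFrame  # one row per k
    ranking: list[str]  # all features, importance-descending
    chosen_k: int | None
    chosen_features: list[str]
    status: str  # "passed" | "none_passed"
    cumulative_importance: float | None  # share at chosen_k
    criteria: dict = field(default_factory=dict)  # k -> CriteriaResult


def _derive_seed(base_seed: int, k: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence((base_seed, k, salt)).generate_state(1)[0])


def choose_k(pass_by_k: dict[int, bool], stability_window: int = 0) -> int | None:
    """Smallest k whose criteria pass (and keep passing through k+window)."""
    for k in sorted(pass_by_k):
        if not pass_by_k[k]:
            continue
        if all(pass_by_k.get(k + j, False) for j in range(1, stability_window + 1)):
            return int(k)
    return None


def simplify_signature(
    train_panel: CellLinePanel,
    cohorts: PatientCohort | list[PatientCohort],
    treatment_col: str = "chemo",
    max_k: int | None = None,
    base_seed: int = 0,
    n_members: int = 500,
    n_estimators: int = 100,
    split_ratio: float = 0.8,
    stability_window: int = 0,
    stop_on_pass: bool = False,
    confident_only: bool = False,
) -> SelectionTrace:
    """Forward feature-inclusion loop driven by the treatment criteria.

    The panel is split 8:2 (seeded from ``base_seed``); the training
    portion feeds every ensemble. Ranking comes from a full-feature
    ensemble and is frozen; importance ties break by feature name. With
    ``stability_window`` w > 0 the criteria must also hold at k+1..k+w
    before a k is chosen. Multiple cohorts must all pass.
    """
    if isinstance(cohorts, PatientCohort):
        cohorts = [cohorts]
    all_features = train_panel.matrix.feature_names
    if max_k is None:
        max_k = len(all_features)
    if max_k > len(all_features):
        raise ValueError("max_k exceeds the number of available features")
    for cohort in cohorts:
        t = cohort.clinical[treatment_col]
        if t.nunique() < 2:
            raise ValueError(
                f"cohort {cohort.matrix.cohort} lacks treated or untreated patients"
            )
        if cohort.clinical["os_event"].sum() == 0:
            raise ValueError(f"cohort {cohort.matrix.cohort} has no events")

    # Panel-side preprocessing and the frozen importance ranking.
    panel_norm = CellLinePanel(
        matrix=zscore_normalize(train_panel.matrix),
        labels=train_panel.labels,
        line_ids=train_panel.line_ids,
        informative_features=train_panel.informative_features,
        spec=train_panel.spec,
    )
    train, val = split_train_validation(
        panel_norm, ratio=split_ratio, seed=_derive_seed(base_seed, 0, salt=1)
    )
    full_model = train_ensemble(
        train,
        n_members=n_members,
        n_estimators=n_estimators,
        seed=_derive_seed(base_seed, 0, salt=2),
    )
    ranking = full_model.ranked_features()
    importance = full_model.importance / full_model.importance.sum()

    cohort_norm = [zscore_normalize(c.matrix) for c in cohorts]

    rows = []
    criteria_by_k: dict[int, object] = {}
    pass_by_k: dict[int, bool] = {}
    for k in range(1, max_k + 1):
        feats = ranking[:k]
        model_k = train_ensemble(
            train,
            n_members=n_members,
            n_estimators=n_estimators,
            seed=_derive_seed(base_seed, k),
            features=feats,
        )
        val_calls = predict_subgroup(
            model_k, select_features(val.matrix, feats), strict=False
        )
        val_metrics = evaluate_classifier(val_calls, val.labels)

        k_pass = True
        crit_last = None
        hr_emt = p_emt = hr_met = p_met = None
        for cohort, cm in zip(cohorts, cohort_norm):
            calls = predict_subgroup(model_k, select_features(cm, feats))
            crit, _ = treatment_effect_by_subgroup(
                cohort.clinical, calls, treatment_col, confident_only=confident_only
            )
            crit_last = crit
            hr_emt, p_emt, hr_met, p_met = crit.hr_emt, crit.p_emt, crit.hr_met, crit.p_met
            if not crit.passed:
                k_pass = False
        criteria_by_k[k] = crit_last
        pass_by_k[k] = k_pass
        rows.append(
            {
                "k": k,
                "added_feature": feats[-1],
                "cumulative_importance": float(importance.loc[feats].sum()),
                "hr_emt": hr_emt,
                "p_emt": p_emt,
                "hr_met": hr_met,
                "p_met": p_met,
                "passed": k_pass,
                "val_accuracy": val_metrics.accuracy,
                "val_f1": val_metrics.f1,
                "val_auc": val_metrics.auc,
            }
        )
        if stop_on_pass and choose_k(pass_by_k, stability_window) is not None:
            break

    records = pd.DataFrame(rows).set_index("k")
    chosen_k = choose_k(pass_by_k, stability_window)
    if chosen_k is None:
        return SelectionTrace(
            records=records,
            ranking=ranking,
            chosen_k=None,
            chosen_features=[],
            status="none_passed",
            cumulative_importance=None,
            criteria=criteria_by_k,
        )
    return SelectionTrace(
        records=records,
        ranking=ranking,
        chosen_k=chosen_k,
        chosen_features=ranking[:chosen_k],
        status="passed",
        cumulative_importance=float(records.loc[chosen_k, "cumulative_importance"]),
        criteria=criteria_by_k,
    )


@dataclass
class StabilityReport:
    selection_frequency: pd.Series  # feature -> share of passing traces selecting it
    chosen_k_values: list[int]
    n_traces: int
    n_passed: int


def stability_report(traces: list[SelectionTrace]) -> StabilityReport:
    """Per-feature selection frequency across seeds plus chosen-k spread."""
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    universe = set(traces[0].ranking)
    for t in traces[1:]:
        if set(t.ranking) != universe:
            raise ValueError("traces cover different feature universes")
    passed = [t for t in traces if t.status == "passed"]
    counts = pd.Series(0.0, index=sorted(universe))
    for t in passed:
        counts.loc[t.chosen_features] += 1.0
    freq = counts / len(passed) if passed else counts
    return StabilityReport(
        selection_frequency=freq.sort_values(ascending=False),
        chosen_k_values=[t.chosen_k for t in passed],
        n_traces=len(traces),
        n_passed=len(passed),
    )
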