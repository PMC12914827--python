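"""Majority-vote random-forest ensemble subgroup classifier.

A configurable number of random-forest members (default 500, each with
100 trees) are trained on bootstrap resamples of the training panel.
A sample's subgroup call is the plurality vote across members and is
flagged confident only when the winning share exceeds the vote
threshold (default 60%). Feature importance is the mean of the members'
impurity importances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .harmonize import ExpressionMatrix
from .synthetic import EMT, METABOLISM, CellLinePanel


@dataclass
class SubgroupCall:
    sample_id: str
    label: str
    vote_fraction: float  # share of members voting the assigned label
    confident: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.vote_fraction <= 1.0:
            raise ValueError("vote_fraction must lie in [0, 1]")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassifierMetrics:
    accuracy: float
    f1: float
    auc: float | None
    counts: ConfusionCounts
    auc_defined: bool = True


@dataclass
class EnsembleModel:
    members: list
    member_seeds: list[int]
    feature_names: list[str]
    classes: tuple[str, str] = (EMT, METABOLISM)
    vote_threshold: float = 0.6
    importance: pd.Series | None = None
    importance_sd: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def ranked_features(self) -> list[str]:
        """Features sorted by mean importance, descending; ties by name."""
        if self.importance is None:
            raise ValueError("model has no importance scores")
        order = sorted(self.importance.index, key=lambda f: (-self.importance[f], f))
        return order


def split_train_validation(
    panel: CellLinePanel,
    ratio: float = 0.8,
    seed: int = 0,
    stratify: bool = False,
    group_by_line: bool = False,
) -> tuple[CellLinePanel, CellLinePanel]:
    """Random train/validation split; validation size = ceil((1-ratio) * n).

    ``stratify`` keeps the class ratio in both portions to within one
    sample; ``group_by_line`` keeps all replicates of a cell line on the
    same side (leakage-safe variant; default mirrors a plain sample-level
    split).
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(panel.matrix.sample_ids)
    n = len(ids)
    n_val = math.ceil((1.0 - ratio) * n)

    if group_by_line:
        lines = panel.line_ids.unique()
        perm = rng.permutation(lines)
        val_ids: list[str] = []
        for ln in perm:
            members = list(panel.line_ids.index[panel.line_ids == ln])
            if len(val_ids) + len(members) <= n_val:
                val_ids.extend(members)
            if len(val_ids) >= n_val:
                break
        val_set = set(val_ids)
    elif stratify:
        val_set = set()
        classes = panel.classes
        # Largest-remainder allocation of the validation quota across classes.
        quotas = {c: (panel.labels == c).sum() * n_val / n for c in classes}
        base = {c: int(math.floor(q)) for c, q in quotas.items()}
        short = n_val - sum(base.values())
        for c in sorted(classes, key=lambda c: quotas[c] - base[c], reverse=True)[:short]:
            base[c] += 1
        for c in classes:
            members = ids[(panel.labels.loc[ids] == c).to_numpy()]
            chosen = rng.choice(members, size=base[c], replace=False)
            val_set.update(chosen)
    else:
        perm = rng.permutation(n)
        val_set = set(ids[perm[:n_val]])

    train_ids = [s for s in ids if s not in val_set]
    val_ids_ordered = [s for s in ids if s in val_set]
    train = _subset_panel(panel, train_ids)
    val = _subset_panel(panel, val_ids_ordered)
    if len(set(train.labels)) < 2:
        raise ValueError("a class is absent from the training portion")
    return train, val


def _subset_panel(panel: CellLinePanel, ids: list[str]) -> CellLinePanel:
    return CellLinePanel(
        matrix=ExpressionMatrix(
            values=panel.matrix.values.loc[ids].copy(),
            cohort=panel.matrix.cohort,
            normalized=panel.matrix.normalized,
            zero_variance=panel.matrix.zero_variance,
        ),
        labels=panel.labels.loc[ids],
        line_ids=panel.line_ids.loc[ids],
        informative_features=panel.informative_features,
        spec=panel.spec,
    )


def train_ensemble(
    train: CellLinePanel,
    n_members: int = 500,
    n_estimators: int = 100,
    seed: int = 0,
    vote_threshold: float = 0.6,
    bootstrap_fraction: float = 1.0,
    features: list[str] | None = None,
) -> EnsembleModel:
    """Train the bootstrap ensemble of random forests.

    Each member is fitted on a with-replacement resample of the training
    samples (size ``bootstrap_fraction`` times the training size) drawn
    with its own seed; resamples are redrawn (deterministically) until
    both classes are present. Mean impurity importance across members is
    recorded along with its SD.
    """
    labels = train.labels
    if len(set(labels)) < 2:
        raise ValueError("training data contains a single class")
    feats = list(features) if features is not None else train.matrix.feature_names
    if not feats:
        raise ValueError("empty feature set")
    X = train.matrix.values.loc[:, feats].to_numpy()
    y = labels.to_numpy()
    n = len(y)
    n_draw = max(2, int(round(bootstrap_fraction * n)))

    member_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_members)]
    members = []
    importances = np.zeros((n_members, len(feats)))
    for mi, ms in enumerate(member_seeds):
        rng = np.random.default_rng(ms)
        for _ in range(100):
            idx = rng.integers(0, n, n_draw)
            if len(set(y[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=ms % (2**31)
        )
        clf.fit(X[idx], y[idx])
        members.append(clf)
        importances[mi] = clf.feature_importances_

    imp_mean = pd.Series(importances.mean(axis=0), index=feats, name="importance")
    imp_sd = pd.Series(importances.std(axis=0, ddof=0), index=feats, name="importance_sd")
    return EnsembleModel(
        members=members,
        member_seeds=member_seeds,
        feature_names=feats,
        vote_threshold=vote_threshold,
        importance=imp_mean,
        importance_sd=imp_sd,
        metadata={
            "n_members": n_members,
            "n_estimators": n_estimators,
            "seed": seed,
            "bootstrap_fraction": bootstrap_fraction,
            "rf_params": RandomForestClassifier(n_estimators=n_estimators).get_params(),
        },
    )


def predict_subgroup(
    model: EnsembleModel, matrix: ExpressionMatrix, strict: bool = False
) -> list[SubgroupCall]:
    """Majority-vote subgroup calls for every sample in the matrix.

    The winning label is the class with more member votes; an exact
    50/50 tie is broken to EMT and flagged non-confident. ``confident``
    requires the winning share to strictly exceed the vote threshold.
    """
    missing = [f for f in model.feature_names if f not in matrix.values.columns]
    if missing:
        raise ValueError(f"matrix lacks model features: {missing}")
    if not matrix.normalized:
        msg = "input matrix is not flagged normalized"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    X = matrix.values.loc[:, model.feature_names].to_numpy()
    n = X.shape[0]
    met_votes = np.zeros(n, dtype=int)
    for member in model.members:
        met_votes += (member.predict(X) == METABOLISM).astype(int)

    calls = []
    total = model.n_members
    for sid, v in zip(matrix.sample_ids, met_votes):
        frac_met = v / total
        if frac_met > 0.5:
            label, frac = METABOLISM, frac_met
        elif frac_met < 0.5:
            label, frac = EMT, 1.0 - frac_met
        else:  # exact tie
            label, frac = EMT, 0.5
        calls.append(
            SubgroupCall(
                sample_id=sid,
                label=label,
                vote_fraction=frac,
                confident=frac > model.vote_threshold,
            )
        )
    return calls


def vote_scores(model: EnsembleModel, calls: list[SubgroupCall]) -> pd.Series:
    """Per-sample metabolism vote share, usable as a ranking score."""
    vals = {
        c.sample_id: c.vote_fraction if c.label == METABOLISM else 1.0 - c.vote_fraction
        for c in calls
    }
    return pd.Series(vals, name="metabolism_score")


def calls_to_frame(calls: list[SubgroupCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "label": [c.label for c in calls],
            "vote_fraction": [c.vote_fraction for c in calls],
            "confident": [c.confident for c in calls],
        }
    ).set_index("sample_id")


def _rank_auc(scores: np.ndarray, truth_pos: np.ndarray) -> float:
    """Probability a random positive outranks a random negative; ties half."""
    n_pos = int(truth_pos.sum())
    n_neg = len(truth_pos) - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    return float((ranks[truth_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_classifier(
    calls: list[SubgroupCall],
    truth: pd.Series,
    positive_label: str = METABOLISM,
    scores: pd.Series | None = None,
) -> ClassifierMetrics:
    """Accuracy, F1 and AUC against known labels.

    Accuracy = (TP+TN)/(TP+TN+FP+FN) and F1 = 2TP/(2TP+FP+FN), with the
    positive class being ``metabolism`` by default. AUC uses the
    metabolism vote share as the ranking score and is flagged undefined
    when the truth contains a single class.
    """
    ids = [c.sample_id for c in calls]
    if set(ids) != set(truth.index):
        raise ValueError("calls and truth cover different sample sets")
    t = truth.loc[ids].to_numpy()
    pred = np.array([c.label for c in calls])
    pos = t == positive_label
    tp = int(((pred == positive_label) & pos).sum())
    tn = int(((pred != positive_label) & ~pos).sum())
    fp = int(((pred == positive_label) & ~pos).sum())
    fn = int(((pred != positive_label) & pos).sum())
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    accuracy = (tp + tn) / counts.total
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0

    if scores is None:
        score_arr = np.array(
            [c.vote_fraction if c.label == positive_label else 1 - c.vote_fraction for c in calls]
        )
    else:
        score_arr = scores.loc[ids].to_numpy()
    if pos.all() or (~pos).all():
        return ClassifierMetrics(accuracy, f1, None, counts, auc_defined=False)
    auc = _rank_auc(score_arr, pos)
    return ClassifierMetrics(accuracy, f1, auc, counts, auc_defined=True)
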