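"""Cross-platform preprocessing of kinase expression matrices.

Feature subsetting, minimum-value imputation, per-cohort z-score
normalisation, and a pooled-PCA cohort dispersion diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class MissingFeaturesError(KeyError):
    """Raised when a required feature is absent from a matrix."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"required features absent: {', '.join(self.missing)}")


@dataclass
class ExpressionMatrix:
    """Samples x features abundance table.

    ``values`` is a float DataFrame indexed by sample ID with feature-name
    columns; missing entries are NaN. ``normalized`` marks that per-feature
    z-scoring has been applied within this cohort.
    """

    values: pd.DataFrame
    cohort: str = "cohort"
    normalized: bool = False
    zero_variance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dupes)}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate feature names: {list(dupes)}")
        self.values = self.values.astype(float)
        self.values.index.name = "sample_id"
        self.values.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


def select_features(matrix: ExpressionMatrix, required_features: list[str]) -> ExpressionMatrix:
    """Restrict a matrix to ``required_features`` in the given order.

    Raises :class:`MissingFeaturesError` naming every absent feature; the
    caller decides whether to shrink the request (this is how a signature
    defined on more kinases is reduced to the subset measured everywhere).
    """
    missing = [f for f in required_features if f not in matrix.values.columns]
    if missing:
        raise MissingFeaturesError(missing)
    return replace(matrix, values=matrix.values.loc[:, list(required_features)].copy())


def impute_minimum(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each missing entry with its feature's observed minimum.

    Raises ``ValueError`` when a feature has no observed value at all.
    """
    vals = matrix.values
    all_missing = [c for c in vals.columns if vals[c].isna().all()]
    if all_missing:
        raise ValueError(f"features entirely missing, cannot impute: {all_missing}")
    filled = vals.fillna(vals.min(axis=0))
    return replace(matrix, values=filled)


def zscore_normalize(matrix: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Per-feature z-score within the cohort (population SD, ddof=0).

    Zero-variance features are set to all-zero and recorded in
    ``zero_variance`` instead of being dropped, so downstream feature
    counts stay fixed. Idempotent on already-normalized input (a warning
    is emitted and the matrix passes through).
    """
    if matrix.normalized:
        warnings.warn("matrix already normalized; returning input unchanged", stacklevel=2)
        return matrix
    if matrix.values.isna().any().any():
        raise ValueError("matrix has missing values; impute before normalising")
    vals = matrix.values
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=ddof)
    flat = sd <= 1e-12
    safe_sd = sd.where(~flat, 1.0)
    out = (vals - mean) / safe_sd
    out.loc[:, flat[flat].index] = 0.0
    return replace(
        matrix,
        values=out,
        normalized=True,
        zero_variance=tuple(flat[flat].index),
    )


def pca_cohort_check(matrices: list[ExpressionMatrix], n_components: int = 2):
    """Pooled PCA of several cohorts plus a cohort-separation summary.

    Returns ``(coords, summary)`` where ``coords`` has columns
    ``sample_id, cohort, pc1, pc2`` and ``summary['pc1_cohort_variance_fraction']``
    is the between-cohort sum of squares of PC1 scores divided by the total
    (a one-way ANOVA decomposition); values near 0 mean no cohort stands
    apart along the leading component.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    ref = matrices[0].feature_names
    for m in matrices[1:]:
        if m.feature_names != ref:
            raise ValueError(
                f"feature sets differ between cohorts ({m.cohort} vs {matrices[0].cohort})"
            )
    pooled = pd.concat([m.values for m in matrices], axis=0)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    cohorts = np.concatenate([[m.cohort] * m.values.shape[0] for m in matrices])

    X = pooled.to_numpy()
    X = X - X.mean(axis=0)
    # SVD-based PCA; deterministic and dependency-free at this scale.
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, vt.shape[0])
    scores = X @ vt[:k].T

    coords = pd.DataFrame(
        {
            "sample_id": pooled.index,
            "cohort": cohorts,
            "pc1": scores[:, 0],
            "pc2": scores[:, 1] if k > 1 else np.zeros(len(pooled)),
        }
    )
    pc1 = coords["pc1"].to_numpy()
    grand = pc1.mean()
    ss_total = float(np.sum((pc1 - grand) ** 2))
    ss_between = 0.0
    for g in np.unique(cohorts):
        sub = pc1[cohorts == g]
        ss_between += len(sub) * (sub.mean() - grand) ** 2
    frac = float(ss_between / ss_total) if ss_total > 0 else 0.0
    summary = {
        "pc1_cohort_variance_fraction": frac,
        "n_samples": int(pooled.shape[0]),
        "n_cohorts": int(len(np.unique(cohorts))),
    }
    return coords, summary
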