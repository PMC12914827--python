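"""Plain-text readers/writers for expression matrices and clinical tables.

Expression matrices travel as TSV (rows = samples, columns = kinases,
index column ``sample_id``); clinical tables as CSV with required
columns ``sample_id``, ``os_months``, ``os_event``. Round-trips preserve
values to full float precision and column order.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .harmonize import ExpressionMatrix

CLINICAL_REQUIRED = ("os_months", "os_event")
CLINICAL_FACTORS = ("sex", "tnm_stage", "lauren", "location")


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression_tsv(path: str | Path, cohort: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate sample IDs in {path}: {list(dup)}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"non-numeric expression columns in {path}: {non_numeric}")
    return ExpressionMatrix(
        values=df.astype(float),
        cohort=cohort if cohort is not None else Path(path).stem,
    )


def write_clinical_csv(clinical: pd.DataFrame, path: str | Path) -> None:
    df = clinical.copy()
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate sample IDs in {path}: {list(dup)}")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table lacks required columns: {missing}")
    bad_event = set(df["os_event"].dropna().unique()) - {0, 1}
    if bad_event:
        raise ValueError(f"os_event must be 0/1; found {sorted(bad_event)}")
    if (df["os_months"].dropna() <= 0).any():
        raise ValueError("os_months must be positive")
    for c in CLINICAL_FACTORS:
        if c in df.columns:
            df[c] = df[c].astype("string").astype(object)
    return df
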