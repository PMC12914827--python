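"""Synthetic cell-line panels and patient cohorts.

Generates data with the structure the downstream analysis assumes: two
latent subgroups (``EMT`` / ``metabolism``) separated on a subset of
kinase-like features, replicate structure for cell lines, and cohort
survival times from an exponential (optionally Weibull) proportional-
hazards model in which treatment benefit may differ by subgroup. All
randomness flows from a single integer seed, so identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .harmonize import ExpressionMatrix

EMT = "EMT"
METABOLISM = "metabolism"

# Generic kinome gene symbols used to label synthetic features.
_KINASE_SYMBOLS = [
    "AAK1", "ABL1", "AKT1", "AURKA", "AURKB", "BRAF", "BTK", "CAMK2D",
    "CDK1", "CDK2", "CDK4", "CDK6", "CHEK1", "CHEK2", "CSNK2A1", "DDR1",
    "EGFR", "EPHA2", "ERBB3", "FGFR1", "FYN", "GSK3B", "ILK", "JAK1",
    "LYN", "MAP2K1", "MAP2K2", "MAPK1", "MAPK3", "MARK2", "MET", "NEK2",
    "PAK1", "PAK2", "PDK1", "PLK1", "PRKACA", "PRKCA", "PTK2", "RET",
    "ROCK1", "RPS6KA1", "SRC", "STK10", "STK39", "SYK", "TGFBR1", "WEE1",
]


def feature_symbols(n_features: int) -> list[str]:
    """Stable kinase-like feature names for a given width."""
    if n_features <= len(_KINASE_SYMBOLS):
        return _KINASE_SYMBOLS[:n_features]
    extra = [f"KIN{i:03d}" for i in range(n_features - len(_KINASE_SYMBOLS))]
    return _KINASE_SYMBOLS + extra


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of the synthetic cell-line panel generator."""

    n_lines: int = 14
    n_replicates: int = 3
    n_features: int = 37
    n_informative: int = 10
    effect_size: float = 2.0  # subgroup mean separation, in marginal-SD units
    replicate_sd: float = 0.5
    line_sd: float = math.sqrt(3.0) / 2.0  # defaults give marginal SD 1
    subgroup_fraction: float = 0.5  # fraction of lines labelled metabolism
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds n_features ({self.n_features})"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_lines < 2 or self.n_replicates < 1:
            raise ValueError("need at least 2 lines and 1 replicate")
        n_met = round(self.subgroup_fraction * self.n_lines)
        if n_met == 0 or n_met == self.n_lines:
            raise ValueError("subgroup_fraction yields an empty class")

    @property
    def n_samples(self) -> int:
        return self.n_lines * self.n_replicates

    @property
    def marginal_sd(self) -> float:
        return math.sqrt(self.line_sd**2 + self.replicate_sd**2)

    def informative_features(self) -> tuple[str, ...]:
        """Deterministic informative-feature subset (depends on seed only)."""
        rng = np.random.default_rng((self.seed, 0xFEA7))
        names = feature_symbols(self.n_features)
        idx = rng.choice(self.n_features, size=self.n_informative, replace=False)
        return tuple(names[i] for i in sorted(idx))


@dataclass
class CellLinePanel:
    """Labelled replicate-level expression panel."""

    matrix: ExpressionMatrix
    labels: pd.Series  # sample_id -> EMT/metabolism
    line_ids: pd.Series  # sample_id -> cell line identifier
    informative_features: tuple[str, ...]
    spec: PanelSpec | None = None

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())


def _subgroup_centers(spec: PanelSpec) -> pd.Series:
    """Half-separation per feature: +c for metabolism, -c for EMT."""
    names = feature_symbols(spec.n_features)
    centers = pd.Series(0.0, index=names)
    half = spec.effect_size * spec.marginal_sd / 2.0
    for f in spec.informative_features():
        centers[f] = half
    return centers


def generate_cellline_panel(spec: PanelSpec) -> CellLinePanel:
    """Simulate a (n_lines * n_replicates) x n_features labelled panel.

    Informative features have subgroup means separated by
    ``effect_size * marginal_sd``; replicates of one line share a
    line-level mean drawn with SD ``line_sd`` and add noise with SD
    ``replicate_sd``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = feature_symbols(spec.n_features)
    centers = _subgroup_centers(spec).to_numpy()

    n_met = round(spec.subgroup_fraction * spec.n_lines)
    line_labels = np.array([METABOLISM] * n_met + [EMT] * (spec.n_lines - n_met))
    rng.shuffle(line_labels)

    rows, sample_ids, labels, line_ids = [], [], [], []
    for li in range(spec.n_lines):
        sign = 1.0 if line_labels[li] == METABOLISM else -1.0
        line_mean = sign * centers + rng.normal(0.0, spec.line_sd, spec.n_features)
        for rep in range(spec.n_replicates):
            rows.append(line_mean + rng.normal(0.0, spec.replicate_sd, spec.n_features))
            sample_ids.append(f"CL{li + 1:02d}_R{rep + 1}")
            labels.append(line_labels[li])
            line_ids.append(f"CL{li + 1:02d}")

    values = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=names)
    matrix = ExpressionMatrix(values=values, cohort="cellline_panel")
    return CellLinePanel(
        matrix=matrix,
        labels=pd.Series(labels, index=sample_ids, name="subgroup"),
        line_ids=pd.Series(line_ids, index=sample_ids, name="line_id"),
        informative_features=spec.informative_features(),
        spec=spec,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic patient-cohort generator.

    Survival times follow a proportional-hazards Weibull model (shape 1 =
    exponential) with baseline rate ``ln 2 / baseline_median_os``; treated
    patients' hazard is multiplied by the subgroup-specific hazard ratio.
    Censoring is administrative at ``admin_censor_time`` only. Clinical
    covariates are generated but carry zero hazard effect unless the
    corresponding knob is set.
    """

    n_patients: int = 600
    subgroup_prevalence: float = 0.5  # probability of metabolism
    treatment_rate: float = 0.4
    hr_treatment_emt: float = 1.0
    hr_treatment_met: float = 0.45
    baseline_median_os: float = 24.0  # months
    admin_censor_time: float = 60.0  # months; inf disables censoring
    weibull_shape: float = 1.0
    panel: PanelSpec = field(default_factory=PanelSpec)
    cohort_name: str = "synthetic_cohort"
    radio_rate: float = 0.0  # optional second treatment flag, no hazard effect
    treatment_rate_met: float | None = None  # confounding knob; None = shared rate
    age_loghr: float = 0.0  # log-HR per year of (age - 63)
    age_loghr_quadratic: float = 0.0  # log-HR per (age - 63)^2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")
        if self.baseline_median_os <= 0:
            raise ValueError("baseline_median_os must be positive")
        if min(self.hr_treatment_emt, self.hr_treatment_met) <= 0:
            raise ValueError("hazard ratios must be positive")
        for r in (self.subgroup_prevalence, self.treatment_rate, self.radio_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class PatientCohort:
    """Expression matrix joined to clinical covariates and outcome.

    ``latent_subgroup`` is the generator's truth and is oracle-only: it
    must never feed the classifier or the survival validation, only
    parameter-recovery tests.
    """

    matrix: ExpressionMatrix
    clinical: pd.DataFrame
    latent_subgroup: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical.index)


def generate_patient_cohort(spec: CohortSpec) -> PatientCohort:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ps = spec.panel
    names = feature_symbols(ps.n_features)
    centers = _subgroup_centers(ps).to_numpy()

    is_met = rng.random(n) < spec.subgroup_prevalence
    sign = np.where(is_met, 1.0, -1.0)
    X = sign[:, None] * centers[None, :] + rng.normal(0.0, ps.marginal_sd, (n, ps.n_features))

    treat_rate = np.where(
        is_met,
        spec.treatment_rate if spec.treatment_rate_met is None else spec.treatment_rate_met,
        spec.treatment_rate,
    )
    chemo = (rng.random(n) < treat_rate).astype(int)
    radio = (rng.random(n) < spec.radio_rate).astype(int)

    age = np.clip(rng.normal(63.0, 10.0, n), 24.0, 90.0)
    sex = rng.choice(["M", "F"], size=n, p=[0.65, 0.35])
    tnm = rng.choice(["II", "III", "IV"], size=n, p=[0.40, 0.38, 0.22])
    lauren = rng.choice(["intestinal", "diffuse", "mixed"], size=n, p=[0.50, 0.40, 0.10])
    location = rng.choice(["cardia", "body", "antrum"], size=n, p=[0.25, 0.40, 0.35])

    hr_treat = np.where(is_met, spec.hr_treatment_met, spec.hr_treatment_emt)
    log_hr = np.where(chemo == 1, np.log(hr_treat), 0.0)
    log_hr = log_hr + spec.age_loghr * (age - 63.0) + spec.age_loghr_quadratic * (age - 63.0) ** 2

    lam = math.log(2.0) / spec.baseline_median_os
    u = rng.random(n)
    # Inverse-CDF draw from S(t) = exp(-(lam t)^k * HR)
    t_raw = (-np.log(u) / np.exp(log_hr)) ** (1.0 / spec.weibull_shape) / lam
    event = (t_raw <= spec.admin_censor_time).astype(int)
    time = np.minimum(t_raw, spec.admin_censor_time)
    time = np.maximum(time, 1e-6)

    ids = [f"{spec.cohort_name}_P{i + 1:05d}" for i in range(n)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(X, index=ids, columns=names), cohort=spec.cohort_name
    )
    clinical = pd.DataFrame(
        {
            "cohort": spec.cohort_name,
            "age": age,
            "sex": sex,
            "tnm_stage": tnm,
            "lauren": lauren,
            "location": location,
            "chemo": chemo,
            "radio": radio,
            "os_months": time,
            "os_event": event,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    latent = pd.Series(
        np.where(is_met, METABOLISM, EMT), index=ids, name="latent_subgroup"
    )
    return PatientCohort(matrix=matrix, clinical=clinical, latent_subgroup=latent)


def inject_missingness(
    matrix: ExpressionMatrix, target_median_rate: float, seed: int
) -> ExpressionMatrix:
    """Mask entries missing completely at random.

    Per-feature missingness rates are drawn around ``target_median_rate``
    (log-uniform jitter with median equal to the target), so the median
    per-feature rate approximates the target while features vary.
    """
    if not 0.0 <= target_median_rate < 1.0:
        raise ValueError("target_median_rate must lie in [0, 1)")
    if target_median_rate == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    vals = matrix.values.copy()
    n, p = vals.shape
    rates = np.clip(target_median_rate * np.exp(rng.uniform(-0.5, 0.5, p)), 0.0, 0.95)
    mask = rng.random((n, p)) < rates[None, :]
    out = vals.mask(pd.DataFrame(mask, index=vals.index, columns=vals.columns))
    return replace(matrix, values=out)
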