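"""Survival analysis and the treatment-benefit validation metric.

Records are pandas DataFrames with ``os_months`` (> 0), ``os_event``
(0/1) and covariate columns (age continuous; sex, TNM stage, Lauren,
location, chemo, radio as factors). All model fits are complete-case:
rows with a missing value in any used column are dropped.

Kaplan–Meier estimation and the log-rank test are delegated to
``lifelines``; Cox models run on the in-house Efron/Newton engine in
:mod:`kinsig.cox`, which also powers the Schoenfeld PH check, the
restricted-cubic-spline linearity test, the multiplicative-interaction
model and the RERI delta-method interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

from . import cox as _cox
from .ensemble import SubgroupCall, calls_to_frame
from .synthetic import EMT, METABOLISM

DURATION_COL = "os_months"
EVENT_COL = "os_event"
ALPHA = 0.05
_Z = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# design-matrix construction


def build_design(records: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, int]:
    """Reference-coded design matrix, complete-case.

    Numeric covariates enter as-is; everything else is expanded to
    indicator columns against the first (sorted) level. Returns the
    design and the number of rows dropped for missingness.
    """
    cols = list(covariates) + [DURATION_COL, EVENT_COL]
    missing_cols = [c for c in cols if c not in records.columns]
    if missing_cols:
        raise KeyError(f"records lack columns: {missing_cols}")
    sub = records.loc[:, cols]
    n_before = len(sub)
    sub = sub.dropna()
    dropped = n_before - len(sub)

    pieces = []
    for c in covariates:
        col = sub[c]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            pieces.append(col.astype(float).rename(c))
        elif pd.api.types.is_numeric_dtype(col):
            pieces.append(col.astype(float).rename(c))  # already 0/1-ish
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                pieces.append((col.astype(str) == lev).astype(float).rename(f"{c}[{lev}]"))
    design = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=sub.index)
    design[DURATION_COL] = sub[DURATION_COL].astype(float)
    design[EVENT_COL] = sub[EVENT_COL].astype(int)
    return design, dropped


# ---------------------------------------------------------------------------
# Cox fit


@dataclass
class CoxFit:
    summary: pd.DataFrame  # term-indexed: coef, se, hr, ci_lower, ci_upper, z, p
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    converged: bool
    flags: list[str]
    cov: pd.DataFrame | None = None
    _times: np.ndarray | None = field(default=None, repr=False)
    _events: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
) -> CoxFit:
    """Cox PH regression with Wald CIs and P values.

    Factors are reference-coded, rows with missing covariates dropped
    (complete-case), ties handled by Efron's method unless ``ties``
    says otherwise.
    """
    design, _ = build_design(records, covariates)
    terms = [c for c in design.columns if c not in (DURATION_COL, EVENT_COL)]
    if not terms:
        raise ValueError("no usable covariates")
    times = design[DURATION_COL].to_numpy()
    events = design[EVENT_COL].to_numpy()
    if np.any(times <= 0):
        raise ValueError("non-positive survival times")
    X = design[terms].to_numpy()
    res = _cox.fit_cox(times, events, X, ties=ties)

    se = np.sqrt(np.diag(res.cov))
    z = res.beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "coef": res.beta,
            "se": se,
            "hr": np.exp(res.beta),
            "ci_lower": np.exp(res.beta - _Z * se),
            "ci_upper": np.exp(res.beta + _Z * se),
            "z": z,
            "p": p,
        },
        index=pd.Index(terms, name="term"),
    )
    return CoxFit(
        summary=summary,
        loglik=res.loglik,
        loglik_null=res.loglik_null,
        n=len(times),
        n_events=int(events.sum()),
        ties=ties,
        converged=res.converged,
        flags=res.flags,
        cov=pd.DataFrame(res.cov, index=terms, columns=terms),
        _times=times,
        _events=events,
        _X=X,
    )


# ---------------------------------------------------------------------------
# KM / log-rank


@dataclass
class KMEstimate:
    curve: pd.DataFrame  # time, survival, ci_lower, ci_upper
    median: float  # months; inf when not reached
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Product-limit survival curve with median OS and its 95% CI."""
    if len(records) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(records[DURATION_COL], records[EVENT_COL])
    ci = kmf.confidence_interval_
    curve = pd.DataFrame(
        {
            "time": kmf.survival_function_.index,
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_lower": ci.iloc[:, 0].to_numpy(),
            "ci_upper": ci.iloc[:, 1].to_numpy(),
        }
    ).reset_index(drop=True)
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(ci)
    lo, hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
    return KMEstimate(
        curve=curve,
        median=median,
        median_ci=(lo, hi),
        n=len(records),
        n_events=int(records[EVENT_COL].sum()),
    )


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int


def logrank_test(records: pd.DataFrame, group_factor) -> LogrankResult:
    """k-group log-rank test; ``group_factor`` is a column name or Series."""
    groups = records[group_factor] if isinstance(group_factor, str) else group_factor.loc[records.index]
    counts = groups.value_counts()
    if (counts > 0).sum() < 2:
        raise ValueError("need at least 2 non-empty groups")
    if records[EVENT_COL].sum() == 0:
        raise ValueError("no events observed in any group")
    res = multivariate_logrank_test(records[DURATION_COL], groups, records[EVENT_COL])
    return LogrankResult(
        statistic=float(res.test_statistic), p=float(res.p_value), df=int(len(counts) - 1)
    )


# ---------------------------------------------------------------------------
# the validation metric


@dataclass
class CriteriaResult:
    """Treatment-benefit selection criteria across the two subgroups.

    ``passed`` holds exactly when HR(EMT) > HR(metabolism), the
    metabolism P value is below alpha and the EMT P value is above it;
    an inestimable entry (None) fails with a recorded reason.
    """

    hr_emt: float | None
    p_emt: float | None
    hr_met: float | None
    p_met: float | None
    passed: bool
    reasons: list[str] = field(default_factory=list)


def evaluate_criteria(
    hr_emt, p_emt, hr_met, p_met, alpha: float = ALPHA
) -> CriteriaResult:
    reasons = []
    estimable = all(v is not None and np.isfinite(v) for v in (hr_emt, p_emt, hr_met, p_met))
    if not estimable:
        reasons.append("inestimable subgroup fit")
        return CriteriaResult(hr_emt, p_emt, hr_met, p_met, False, reasons)
    if not hr_emt > hr_met:
        reasons.append(f"HR ordering violated (EMT {hr_emt:.3g} <= metabolism {hr_met:.3g})")
    if not p_met < alpha:
        reasons.append(f"metabolism P not significant ({p_met:.3g} >= {alpha})")
    if not p_emt > alpha:
        reasons.append(f"EMT P significant ({p_emt:.3g} <= {alpha})")
    return CriteriaResult(hr_emt, p_emt, hr_met, p_met, not reasons, reasons)


def _univariable_treatment_fit(sub: pd.DataFrame, treatment_col: str):
    """Cox of the treatment flag within one subgroup; None when inestimable."""
    if len(sub) < 2:
        return None, "fewer than 2 samples"
    if sub[treatment_col].nunique() < 2:
        return None, f"no variation in {treatment_col}"
    if sub[EVENT_COL].sum() == 0:
        return None, "no events"
    try:
        fit = cox_fit(sub, [treatment_col])
    except (ValueError, np.linalg.LinAlgError) as exc:
        return None, str(exc)
    if "monotone_likelihood" in fit.flags or not fit.converged:
        return None, "monotone likelihood / no convergence"
    return fit, None


def treatment_effect_by_subgroup(
    clinical: pd.DataFrame,
    calls: list[SubgroupCall] | pd.DataFrame,
    treatment_col: str = "chemo",
    confident_only: bool = False,
    alpha: float = ALPHA,
):
    """Per-subgroup univariable treatment Cox fits plus the criteria check.

    Returns ``(criteria, fits)`` where ``fits`` maps subgroup label to its
    CoxFit (or None when inestimable). ``confident_only`` restricts the
    analysis to confident vote calls (sensitivity switch).
    """
    call_df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    common = clinical.index.intersection(call_df.index)
    if len(common) == 0:
        raise ValueError("no overlap between clinical records and subgroup calls")
    merged = clinical.loc[common].copy()
    merged["_subgroup"] = call_df.loc[common, "label"]
    if confident_only:
        merged = merged[call_df.loc[common, "confident"]]

    fits: dict[str, CoxFit | None] = {}
    values: dict[str, float | None] = {}
    reasons: dict[str, str | None] = {}
    for grp in (EMT, METABOLISM):
        sub = merged[merged["_subgroup"] == grp]
        fit, why = _univariable_treatment_fit(sub, treatment_col)
        fits[grp] = fit
        reasons[grp] = why
        if fit is None:
            values[f"hr_{grp}"] = None
            values[f"p_{grp}"] = None
        else:
            values[f"hr_{grp}"] = fit.hr(treatment_col)
            values[f"p_{grp}"] = fit.p(treatment_col)

    criteria = evaluate_criteria(
        values[f"hr_{EMT}"],
        values[f"p_{EMT}"],
        values[f"hr_{METABOLISM}"],
        values[f"p_{METABOLISM}"],
        alpha=alpha,
    )
    for grp, why in reasons.items():
        if why is not None:
            criteria.reasons.append(f"{grp}: {why}")
    return criteria, fits


# ---------------------------------------------------------------------------
# interaction statistics


@dataclass
class InteractionResult:
    coef: float
    hr_ratio: float  # exp(interaction coefficient)
    se: float
    p: float
    fit: CoxFit


def _with_subgroup(clinical: pd.DataFrame, subgroup) -> pd.DataFrame:
    sub = subgroup if isinstance(subgroup, pd.Series) else pd.Series(subgroup)
    df = clinical.copy()
    df["_met"] = (sub.loc[df.index].astype(str) == METABOLISM).astype(int)
    return df


def multiplicative_interaction(
    clinical: pd.DataFrame,
    subgroup,
    treatment_col: str = "chemo",
    adjust_covariates: tuple[str, ...] = (),
) -> InteractionResult:
    """Cox model with subgroup, treatment and their product term."""
    df = _with_subgroup(clinical, subgroup)
    cells = df.groupby(["_met", treatment_col])[EVENT_COL].sum()
    if len(cells) < 4 or (cells == 0).any():
        raise ValueError("empty or eventless subgroup x treatment cell")
    df["_treat"] = df[treatment_col].astype(int)
    df["_inter"] = df["_met"] * df["_treat"]
    fit = cox_fit(df, ["_met", "_treat", "_inter", *adjust_covariates])
    row = fit.summary.loc["_inter"]
    return InteractionResult(
        coef=float(row["coef"]),
        hr_ratio=float(row["hr"]),
        se=float(row["se"]),
        p=float(row["p"]),
        fit=fit,
    )


def reri_from_hrs(hr10: float, hr01: float, hr11: float) -> float:
    """RERI = HR11 - HR10 - HR01 + 1 (zero under risk-scale additivity)."""
    return hr11 - hr10 - hr01 + 1.0


@dataclass
class RERIResult:
    reri: float
    se: float
    ci: tuple[float, float]
    p: float
    hr10: float
    hr01: float
    hr11: float
    fit: CoxFit


def reri(
    clinical: pd.DataFrame,
    subgroup,
    treatment_col: str = "chemo",
    adjust_covariates: tuple[str, ...] = (),
) -> RERIResult:
    """Relative excess risk due to interaction, delta-method CI.

    Fits a Cox model with indicators for (subgroup only), (treatment
    only) and (both) against the doubly-unexposed reference; RERI =
    HR11 - HR10 - HR01 + 1, with variance from the coefficient
    covariance via the delta method.
    """
    df = _with_subgroup(clinical, subgroup)
    t = df[treatment_col].astype(int)
    df["_x10"] = ((df["_met"] == 1) & (t == 0)).astype(int)
    df["_x01"] = ((df["_met"] == 0) & (t == 1)).astype(int)
    df["_x11"] = ((df["_met"] == 1) & (t == 1)).astype(int)
    cells = df.groupby(["_met", t])[EVENT_COL].count()
    if len(cells) < 4 or (cells == 0).any():
        raise ValueError("empty exposure cell")
    fit = cox_fit(df, ["_x10", "_x01", "_x11", *adjust_covariates])
    hr10 = fit.hr("_x10")
    hr01 = fit.hr("_x01")
    hr11 = fit.hr("_x11")
    val = reri_from_hrs(hr10, hr01, hr11)
    grad = np.zeros(len(fit.cov))
    terms = list(fit.cov.index)
    grad[terms.index("_x10")] = -hr10
    grad[terms.index("_x01")] = -hr01
    grad[terms.index("_x11")] = hr11
    var = float(grad @ fit.cov.to_numpy() @ grad)
    if not np.isfinite(var) or var <= 0:
        raise ValueError("inestimable covariance for RERI")
    se = math.sqrt(var)
    p = 2 * stats.norm.sf(abs(val) / se)
    return RERIResult(
        reri=val,
        se=se,
        ci=(val - _Z * se, val + _Z * se),
        p=p,
        hr10=hr10,
        hr01=hr01,
        hr11=hr11,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# assumption checks


def _km_survival_at(times: np.ndarray, events: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Left-continuous KM survival evaluated at the given times."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = len(t)
    surv = 1.0
    uniq_t, uniq_s = [], []
    i = 0
    while i < n:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += e[j]
            j += 1
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
            uniq_t.append(t[i])
            uniq_s.append(surv)
        i = j
    uniq_t = np.asarray(uniq_t)
    uniq_s = np.asarray(uniq_s)
    idx = np.searchsorted(uniq_t, at, side="right") - 1
    out = np.where(idx >= 0, uniq_s[np.clip(idx, 0, None)], 1.0)
    return out


@dataclass
class PHCheckResult:
    per_covariate: pd.DataFrame  # term-indexed: statistic, p
    global_statistic: float
    global_p: float
    transform: str


def ph_check_schoenfeld(fit: CoxFit, transform: str = "km") -> PHCheckResult:
    """Grambsch–Therneau test of the PH assumption from scaled Schoenfeld
    residuals against a transform of event time ('km', 'rank' or
    'identity')."""
    if fit._X is None:
        raise ValueError("fit does not carry its design (refit with cox_fit)")
    p_dim = fit._X.shape[1]
    m = int(fit._events.sum())
    if m < p_dim + 2:
        raise ValueError("too few events for the PH check")
    ts, resid = _cox.schoenfeld_residuals(
        fit._times, fit._events, fit._X, np.log(fit.summary["hr"].to_numpy())
    )
    if transform == "km":
        g = 1.0 - _km_survival_at(fit._times, fit._events, ts)
    elif transform == "rank":
        g = stats.rankdata(ts)
    elif transform == "identity":
        g = ts.astype(float)
    else:
        raise ValueError(f"unknown transform: {transform}")
    gc = g - g.mean()
    u = gc @ resid  # p-vector
    info = np.linalg.inv(fit.cov.to_numpy())  # observed information
    vbar = info / m
    denom = float(gc @ gc)
    per_stat = u**2 / (denom * np.diag(vbar))
    per_p = stats.chi2.sf(per_stat, df=1)
    global_stat = float(u @ np.linalg.solve(denom * vbar, u))
    global_p = float(stats.chi2.sf(global_stat, df=p_dim))
    per = pd.DataFrame(
        {"statistic": per_stat, "p": per_p}, index=fit.summary.index
    )
    return PHCheckResult(per, global_stat, global_p, transform)


def rcs_basis(x: np.ndarray, knots: tuple[float, float, float]) -> np.ndarray:
    """Nonlinear basis column of a 3-knot restricted cubic spline."""
    k1, k2, k3 = knots
    cube = lambda k: np.maximum(x - k, 0.0) ** 3  # noqa: E731
    b = cube(k1) - cube(k2) * (k3 - k1) / (k3 - k2) + cube(k3) * (k2 - k1) / (k3 - k2)
    return b / (k3 - k1) ** 2


@dataclass
class RCSLinearityResult:
    lr_statistic: float
    df: int
    p: float
    knots: tuple[float, float, float]


def linearity_check_rcs(
    records: pd.DataFrame,
    continuous_covariate: str,
    adjust_covariates: tuple[str, ...] = (),
) -> RCSLinearityResult:
    """Likelihood-ratio comparison of a linear Cox term against a 3-knot
    restricted cubic spline (knots at the 10th/50th/90th percentiles)."""
    sub = records.dropna(subset=[continuous_covariate, DURATION_COL, EVENT_COL]).copy()
    x = sub[continuous_covariate].astype(float)
    if x.nunique() < 4:
        raise ValueError("need at least 4 distinct covariate values for 3 knots")
    knots = tuple(np.percentile(x, [10, 50, 90]))
    if len(set(knots)) < 3:
        raise ValueError("degenerate knot placement (ties at percentiles)")
    fit_lin = cox_fit(sub, [continuous_covariate, *adjust_covariates])
    sub["_rcs"] = rcs_basis(x.to_numpy(), knots)
    fit_spl = cox_fit(sub, [continuous_covariate, "_rcs", *adjust_covariates])
    lr = 2.0 * (fit_spl.loglik - fit_lin.loglik)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return RCSLinearityResult(lr_statistic=float(lr), df=1, p=p, knots=knots)


# ---------------------------------------------------------------------------
# gated baseline comparison battery


def baseline_comparison(
    clinical: pd.DataFrame,
    subgroup,
    variables: list[str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Two-group baseline table tests with assumption gates.

    Continuous variables: Student's t when both groups pass Shapiro–Wilk
    normality (P >= 0.05) and Levene's equal-variance test (P >= 0.05),
    otherwise the Wilcoxon rank-sum test. Categorical variables: Pearson
    chi-square when all expected counts are >= 5, otherwise Fisher's
    exact test (2x2). All tests two-sided.
    """
    sub = subgroup if isinstance(subgroup, pd.Series) else pd.Series(subgroup)
    sub = sub.loc[clinical.index]
    labels = sorted(sub.unique())
    if len(labels) != 2:
        raise ValueError("need exactly two subgroups")
    if variables is None:
        variables = [
            v
            for v in ("age", "sex", "tnm_stage", "lauren", "location", "chemo", "radio")
            if v in clinical.columns
        ]

    rows = []
    for var in variables:
        col = clinical[var]
        if col.dropna().nunique() < 2:
            raise ValueError(f"variable constant in both groups: {var}")
        continuous = pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 5
        a = col[sub == labels[0]].dropna()
        b = col[sub == labels[1]].dropna()
        note = ""
        if continuous:
            sw_a = stats.shapiro(a.sample(min(len(a), 5000), random_state=0)).pvalue
            sw_b = stats.shapiro(b.sample(min(len(b), 5000), random_state=0)).pvalue
            lev = stats.levene(a, b, center="mean").pvalue
            if sw_a >= alpha and sw_b >= alpha and lev >= alpha:
                test = "student_t"
                stat, p = stats.ttest_ind(a, b, equal_var=True)
            else:
                test = "wilcoxon_ranksum"
                stat, p = stats.ranksums(a, b)
            rows.append((var, "continuous", test, float(stat), float(p), note))
        else:
            table = pd.crosstab(col.astype(str), sub)
            expected = stats.contingency.expected_freq(table.to_numpy())
            if (expected >= 5).all():
                test = "pearson_chi2"
                stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            elif table.shape == (2, 2):
                test = "fisher_exact"
                stat, p = stats.fisher_exact(table.to_numpy())
            else:
                test = "pearson_chi2"
                note = "expected count < 5 but table exceeds 2x2; Fisher unavailable"
                stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            rows.append((var, "categorical", test, float(stat), float(p), note))
    return pd.DataFrame(
        rows, columns=["variable", "kind", "test", "statistic", "p", "note"]
    ).set_index("variable")
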