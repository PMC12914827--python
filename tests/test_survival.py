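import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import exp_survival_frame
from kinsig.survival import (
    baseline_comparison,
    cox_fit,
    evaluate_criteria,
    km_estimate,
    linearity_check_rcs,
    logrank_test,
    multiplicative_interaction,
    ph_check_schoenfeld,
    reri,
    reri_from_hrs,
    treatment_effect_by_subgroup,
)
from kinsig.synthetic import (
    EMT,
    METABOLISM,
    CohortSpec,
    generate_patient_cohort,
)


class TestKaplanMeier:
    def test_uncensored_sequence_median(self):
        df = pd.DataFrame({"os_months": [1.0, 2.0, 3.0, 4.0, 5.0], "os_event": 1})
        assert km_estimate(df).median == 3.0

    def test_all_censored_median_not_reached(self):
        df = pd.DataFrame({"os_months": [5.0, 8.0, 9.0], "os_event": 0})
        est = km_estimate(df)
        assert not est.median_reached

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(pd.DataFrame({"os_months": [], "os_event": []}))

    def test_median_ci_brackets_median(self):
        rng = np.random.default_rng(0)
        df = exp_survival_frame(rng, 300, np.zeros(300))
        est = km_estimate(df)
        assert est.median_ci[0] <= est.median <= est.median_ci[1]


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        base = pd.DataFrame({"os_months": [2.0, 4.0, 6.0, 8.0], "os_event": [1, 0, 1, 1]})
        df = pd.concat([base, base], ignore_index=True)
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        res = logrank_test(df, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"os_months": [1.0, 2.0], "os_event": [1, 1]})
        with pytest.raises(ValueError, match="non-empty groups"):
            logrank_test(df, pd.Series(["a", "a"]))

    def test_eventless_data_rejected(self):
        df = pd.DataFrame({"os_months": [1.0, 2.0], "os_event": [0, 0]})
        with pytest.raises(ValueError, match="no events"):
            logrank_test(df, pd.Series(["a", "b"]))

    def test_hr2_arms_powerful_and_agrees_with_cox_oracle(self):
        # Oracle: Cox Wald test on the same data.
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.repeat([0.0, 1.0], 500)
            df = exp_survival_frame(rng, 1000, math.log(2.0) * x)
            df["x"] = x
            res = logrank_test(df, pd.Series(np.where(x == 1, "b", "a")))
            if res.p < 0.001:
                hits += 1
            if seed < 20:  # Wald agreement on a subset (runtime)
                fit = cox_fit(df, ["x"])
                assert (res.p < 0.05) == (fit.p("x") < 0.05)
        assert hits >= 95

    def test_logrank_cox_significance_agreement(self):
        agree = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(10_000 + seed)
            x = (rng.random(300) < 0.5).astype(float)
            df = exp_survival_frame(rng, 300, 0.3 * x)
            df["x"] = x
            lr = logrank_test(df, pd.Series(np.where(x == 1, "b", "a")))
            fit = cox_fit(df, ["x"])
            if (lr.p < 0.05) == (fit.p("x") < 0.05):
                agree += 1
        assert agree / n_sims >= 0.95


class TestCriteria:
    def test_reported_values_pass(self):
        res = evaluate_criteria(hr_emt=0.77, p_emt=0.30, hr_met=0.45, p_met=0.0077)
        assert res.passed

    def test_hr_ordering_violation_fails_with_reason(self):
        res = evaluate_criteria(hr_emt=0.40, p_emt=0.30, hr_met=0.50, p_met=0.001)
        assert not res.passed
        assert any("ordering" in r for r in res.reasons)

    def test_inestimable_entries_fail(self):
        res = evaluate_criteria(None, None, 0.4, 0.01)
        assert not res.passed

    @given(
        hr_emt=st.floats(0.01, 10.0),
        p_emt=st.floats(0.0, 1.0),
        hr_met=st.floats(0.01, 10.0),
        p_met=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_pass_iff_invariant(self, hr_emt, p_emt, hr_met, p_met):
        res = evaluate_criteria(hr_emt, p_emt, hr_met, p_met)
        assert res.passed == ((hr_emt > hr_met) and (p_met < 0.05) and (p_emt > 0.05))


class TestTreatmentEffectBySubgroup:
    def test_benefit_only_in_metabolism_passes(self, std_cohort):
        calls = pd.DataFrame(
            {"label": std_cohort.latent_subgroup, "confident": True}
        ).rename_axis("sample_id")
        criteria, fits = treatment_effect_by_subgroup(std_cohort.clinical, calls)
        assert criteria.passed, criteria.reasons
        assert fits[METABOLISM].hr("chemo") < fits[EMT].hr("chemo")

    def test_all_treated_subgroup_inestimable_not_crash(self, std_cohort):
        clinical = std_cohort.clinical.copy()
        met = std_cohort.latent_subgroup == METABOLISM
        clinical.loc[met, "chemo"] = 1  # metabolism arm has no untreated patients
        calls = pd.DataFrame(
            {"label": std_cohort.latent_subgroup, "confident": True}
        ).rename_axis("sample_id")
        criteria, fits = treatment_effect_by_subgroup(clinical, calls)
        assert not criteria.passed
        assert fits[METABOLISM] is None

    def test_disjoint_samples_rejected(self, std_cohort):
        calls = pd.DataFrame(
            {"label": [EMT], "confident": [True]}, index=pd.Index(["nope"], name="sample_id")
        )
        with pytest.raises(ValueError, match="no overlap"):
            treatment_effect_by_subgroup(std_cohort.clinical, calls)


def _latent_calls(cohort):
    return pd.DataFrame(
        {"label": cohort.latent_subgroup, "confident": True}
    ).rename_axis("sample_id")


class TestMultiplicativeInteraction:
    def test_null_interaction_near_zero_large_n(self):
        cohort = generate_patient_cohort(
            CohortSpec(n_patients=20000, hr_treatment_met=0.6, hr_treatment_emt=0.6, seed=31)
        )
        res = multiplicative_interaction(cohort.clinical, cohort.latent_subgroup)
        assert abs(res.coef) < 0.05

    def test_ratio_of_stratum_hrs_recovered(self):
        cohort = generate_patient_cohort(CohortSpec(n_patients=20000, seed=32))
        res = multiplicative_interaction(cohort.clinical, cohort.latent_subgroup)
        assert 0.40 <= res.hr_ratio <= 0.50

    def test_empty_cell_rejected(self):
        cohort = generate_patient_cohort(CohortSpec(n_patients=300, seed=33))
        clinical = cohort.clinical.copy()
        met = cohort.latent_subgroup == METABOLISM
        clinical.loc[met, "chemo"] = 0
        with pytest.raises(ValueError, match="cell"):
            multiplicative_interaction(clinical, cohort.latent_subgroup)


class TestRERI:
    def test_additive_identity_gives_zero(self):
        assert reri_from_hrs(1.3, 1.9, 1.3 + 1.9 - 1.0) == pytest.approx(0.0)

    def test_delta_ci_close_to_bootstrap(self):
        cohort = generate_patient_cohort(
            CohortSpec(n_patients=800, hr_treatment_met=0.6, hr_treatment_emt=1.0, seed=40)
        )
        res = reri(cohort.clinical, cohort.latent_subgroup)
        half_delta = (res.ci[1] - res.ci[0]) / 2.0

        rng = np.random.default_rng(41)
        vals = []
        clinical = cohort.clinical
        latent = cohort.latent_subgroup
        for _ in range(1000):
            idx = rng.integers(0, len(clinical), len(clinical))
            boot = clinical.iloc[idx].reset_index(drop=True)
            boot.index = [f"b{i}" for i in range(len(boot))]
            sub = pd.Series(latent.iloc[idx].to_numpy(), index=boot.index)
            try:
                vals.append(reri(boot, sub).reri)
            except (ValueError, np.linalg.LinAlgError):
                continue
        half_boot = 1.96 * np.std(vals, ddof=1)
        assert abs(half_delta - half_boot) / half_boot < 0.15

    def test_empty_cell_rejected(self):
        cohort = generate_patient_cohort(CohortSpec(n_patients=200, seed=42))
        clinical = cohort.clinical.copy()
        clinical["chemo"] = 1
        with pytest.raises(ValueError):
            reri(clinical, cohort.latent_subgroup)


class TestSchoenfeldCheck:
    def test_constant_covariate_cannot_be_fit(self):
        df = pd.DataFrame({"os_months": [1.0, 2.0, 3.0], "os_event": 1, "x": 1.0})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "os_months": rng.exponential(10, 40),
                "os_event": [1, 1] + [0] * 38,
                "x": rng.normal(size=40),
            }
        )
        fit = cox_fit(df, ["x"])
        with pytest.raises(ValueError, match="too few events"):
            ph_check_schoenfeld(fit)

    def test_power_against_sign_flipping_effect(self):
        # Hazard effect +b before the time horizon's midpoint, -b after.
        b, tau, horizon = 0.8, 10.0, 30.0
        rejections = 0
        n_sims = 50
        for seed in range(n_sims):
            rng = np.random.default_rng(500 + seed)
            n = 1000
            x = (rng.random(n) < 0.5).astype(float)
            lam = np.log(2.0) / 20.0
            t1 = rng.exponential(1.0 / (lam * np.exp(b * x)))
            # memoryless restart with the flipped effect after tau
            tail = rng.exponential(1.0 / (lam * np.exp(-b * x)))
            t = np.where(t1 <= tau, t1, tau + tail)
            event = (t <= horizon).astype(int)
            df = pd.DataFrame({"os_months": np.minimum(t, horizon), "os_event": event, "x": x})
            fit = cox_fit(df, ["x"])
            if ph_check_schoenfeld(fit).per_covariate.loc["x", "p"] < 0.05:
                rejections += 1
        assert rejections / n_sims > 0.8


class TestRCSLinearity:
    def test_three_distinct_values_rejected(self):
        df = pd.DataFrame(
            {
                "os_months": np.arange(1.0, 13.0),
                "os_event": 1,
                "age": [50.0, 60.0, 70.0] * 4,
            }
        )
        with pytest.raises(ValueError, match="distinct"):
            linearity_check_rcs(df, "age")

    def test_power_against_quadratic_effect(self):
        rejections = 0
        n_sims = 40
        for seed in range(n_sims):
            cohort = generate_patient_cohort(
                CohortSpec(n_patients=1500, age_loghr_quadratic=0.003, seed=600 + seed)
            )
            res = linearity_check_rcs(cohort.clinical, "age")
            if res.p < 0.05:
                rejections += 1
        assert rejections / n_sims > 0.8


class TestBaselineComparison:
    def test_gaussian_equal_variance_selects_t_test(self):
        rng = np.random.default_rng(0)
        n = 400
        clinical = pd.DataFrame(
            {"age": rng.normal(60, 10, n)}, index=[f"s{i}" for i in range(n)]
        )
        sub = pd.Series(np.where(np.arange(n) % 2 == 0, EMT, METABOLISM), index=clinical.index)
        out = baseline_comparison(clinical, sub, variables=["age"])
        assert out.loc["age", "test"] == "student_t"

    def test_small_expected_count_selects_fisher(self):
        # 2x2 with an expected count of 3.
        labels = [EMT] * 30 + [METABOLISM] * 30
        flag = [1] * 6 + [0] * 24 + [1] * 0 + [0] * 30
        clinical = pd.DataFrame(
            {"rare": pd.Categorical(flag)}, index=[f"s{i}" for i in range(60)]
        )
        sub = pd.Series(labels, index=clinical.index)
        out = baseline_comparison(clinical, sub, variables=["rare"])
        assert out.loc["rare", "test"] == "fisher_exact"

    def test_skewed_variable_selects_ranksum(self):
        rng = np.random.default_rng(1)
        n = 300
        clinical = pd.DataFrame(
            {"marker": rng.lognormal(0, 1.5, n)}, index=[f"s{i}" for i in range(n)]
        )
        sub = pd.Series(np.where(np.arange(n) % 2 == 0, EMT, METABOLISM), index=clinical.index)
        out = baseline_comparison(clinical, sub, variables=["marker"])
        assert out.loc["marker", "test"] == "wilcoxon_ranksum"

    def test_constant_variable_rejected(self):
        clinical = pd.DataFrame({"flat": [1, 1, 1, 1]}, index=list("abcd"))
        sub = pd.Series([EMT, EMT, METABOLISM, METABOLISM], index=clinical.index)
        with pytest.raises(ValueError, match="constant"):
            baseline_comparison(clinical, sub, variables=["flat"])

    def test_p_values_match_manual_reference(self):
        # Manual formulas, independent of the scipy calls in the module.
        from scipy import stats as ss

        rng = np.random.default_rng(7)
        n = 200
        idx = [f"s{i}" for i in range(n)]
        sub = pd.Series(np.where(rng.random(n) < 0.5, EMT, METABOLISM), index=idx)
        cont = {f"v{j}": rng.normal(0, 1, n) for j in range(25)}
        cat = {f"c{j}": rng.choice(["x", "y"], n) for j in range(25)}
        clinical = pd.DataFrame({**cont, **cat}, index=idx)
        out = baseline_comparison(clinical, sub, variables=list(clinical.columns))
        a_mask = (sub == EMT).to_numpy()
        for j in range(25):
            row = out.loc[f"v{j}"]
            a = clinical[f"v{j}"].to_numpy()[a_mask]
            b = clinical[f"v{j}"].to_numpy()[~a_mask]
            if row["test"] == "student_t":
                na, nb = len(a), len(b)
                sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
                tstat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
                p_ref = 2 * ss.t.sf(abs(tstat), na + nb - 2)
            else:
                ranks = ss.rankdata(np.concatenate([a, b]))
                ra = ranks[: len(a)].sum()
                na, nb = len(a), len(b)
                mu = na * (na + nb + 1) / 2
                sigma = math.sqrt(na * nb * (na + nb + 1) / 12.0)
                p_ref = 2 * ss.norm.sf(abs((ra - mu) / sigma))
            assert abs(row["p"] - p_ref) < 1e-6
        for j in range(25):
            row = out.loc[f"c{j}"]
            table = pd.crosstab(clinical[f"c{j}"], sub).to_numpy()
            rowsum = table.sum(axis=1, keepdims=True)
            colsum = table.sum(axis=0, keepdims=True)
            expected = rowsum @ colsum / table.sum()
            chi2 = ((table - expected) ** 2 / expected).sum()
            dof = (table.shape[0] - 1) * (table.shape[1] - 1)
            p_ref = ss.chi2.sf(chi2, dof)
            assert abs(row["p"] - p_ref) < 1e-6
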