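"""Cohort ingestion, crosstabs, logistic/LRT machinery, and the EOR model."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metseed import epi, fixtures
from metseed.epi import ExcessOddsRatioLogit


def cohort_frame(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "id": [f"s{i}" for i in range(n)],
        "sex": ["F"] * n,
        "age_at_ptc": [30.0] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestIngestCohort:
    def test_dose_truncation(self):
        df = cohort_frame(dose_mGy=[8800.0, 247.0, 0.0], clnm=[True, False, False])
        out, _ = epi.ingest_cohort(df)
        assert out["dose_Gy_trunc"].tolist() == [1.0, 0.247, 0.0]

    def test_nx_recode_to_n0(self):
        df = cohort_frame(n_stage=["Nx", "N1a", "N0"])
        out, _ = epi.ingest_cohort(df)
        assert out["n_stage"].tolist() == ["N0", "N1A", "N0"]
        assert out["clnm"].tolist() == [False, True, False]

    def test_mm_recode_to_m0(self):
        df = cohort_frame(n_stage=["N0"], m_stage=["Mm"])
        out, _ = epi.ingest_cohort(df)
        assert out["m_stage"].iloc[0] == "M0"

    def test_missing_sex_row_rejected_with_reason(self):
        df = cohort_frame(clnm=[True, False])
        df.loc[0, "sex"] = None
        kept, rejected = epi.ingest_cohort(df)
        assert len(kept) == 1
        assert rejected["reject_reason"].iloc[0] == "missing_sex"

    def test_missing_required_column_error(self):
        with pytest.raises(ValueError, match="missing required"):
            epi.ingest_cohort(pd.DataFrame({"id": ["a"]}))


class TestCrosstab:
    def test_reference_percentages(self):
        ct = epi.crosstab(fixtures.reference_driver_cohort())
        expected = {
            "RET_fusion": 71.2,
            "other_RTK_fusion": 64.1,
            "other_fusion": 10.3,
            "BRAF_mutation": 37.6,
            "other_mutation": 5.2,
        }
        for cat, pct in expected.items():
            assert ct.loc[cat, "pct"] == pct

    def test_mechanism_aggregation(self):
        ct = epi.crosstab(fixtures.reference_driver_cohort(), row="mechanism")
        assert ct.loc["mutation", "pct"] == 30.2
        assert ct.loc["fusion", "pct"] == 55.1

    def test_partner_level(self):
        ref = fixtures.reference_driver_cohort()
        sub = ref[ref["partner_group"].notna()]
        ct = epi.crosstab(sub, row="partner_group")
        assert ct.loc["NCOA4_RET", "pct"] == 80.0
        assert ct.loc["NTRK1", "pct"] == 84.6
        assert ct.loc["CCDC6_RET", "pct"] == 65.0

    def test_zero_event_row(self):
        df = cohort_frame(driver_category=["X"] * 4, clnm=[False] * 4)
        ct = epi.crosstab(df)
        assert ct.loc["X", "pct"] == 0.0

    def test_single_category_equals_prevalence(self):
        df = cohort_frame(driver_category=["X"] * 10, clnm=[True] * 3 + [False] * 7)
        ct = epi.crosstab(df)
        assert ct.loc["X", "pct"] == 30.0

    def test_split_column(self):
        stg = fixtures.reference_staging_cohort()
        stg["all"] = "cohort"
        ct = epi.crosstab(stg, row="all", col="clnm", split_col="n_stage")
        assert ct.loc["cohort", "pct"] == 40.5  # 178/440 nodal-positive
        assert ct.loc["cohort", "n_N1a"] == 87


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # exposed: 10 events / 10 non; unexposed: 5 events / 20 non -> OR = 4
        y = [1] * 10 + [0] * 10 + [1] * 5 + [0] * 20
        x = [1.0] * 20 + [0.0] * 25
        fit = epi.fit_logistic(y, pd.DataFrame({"exposed": x}))
        assert fit.params["exposed"] == pytest.approx(math.log(4.0), abs=1e-6)
        assert fit.odds_ratios.loc["exposed", "OR"] == pytest.approx(4.0, rel=1e-5)

    def test_independent_covariate_coefficient_zero(self):
        y = ([1, 0] * 10)
        x = [1.0] * 10 + [0.0] * 10
        fit = epi.fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-8)

    def test_loglik_matches_grid_oracle(self, rng):
        """ML loglik beats every point of a brute-force grid on toy data."""
        n = 30
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + 0.8 * x)))).astype(float)
        fit = epi.fit_logistic(y, pd.DataFrame({"x": x}))

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return np.sum(y * eta - np.logaddexp(0, eta))

        grid_best = max(
            loglik(b0, b1)
            for b0 in np.linspace(-2, 2, 81)
            for b1 in np.linspace(-2, 3, 101)
        )
        assert fit.loglik >= grid_best - 1e-6

    def test_complete_separation_aborts(self):
        y = [1] * 5 + [0] * 5
        x = [1.0] * 5 + [0.0] * 5
        with pytest.raises(ValueError, match="separation"):
            epi.fit_logistic(y, pd.DataFrame({"x": x}))


class TestLRT:
    def test_identical_models(self):
        res = epi.lrt(-10.0, -10.0, df=1)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_chi_square_quantile_identity(self):
        res = epi.lrt(-8.0795, -10.0, df=1)  # statistic 3.841
        assert res.p == pytest.approx(0.05, abs=1e-3)

    def test_clamped_at_zero_under_numeric_noise(self):
        res = epi.lrt(-10.0 - 1e-12, -10.0, df=1)
        assert res.statistic == 0.0

    def test_non_nested_error(self):
        with pytest.raises(ValueError):
            epi.lrt(-9.0, -10.0, df=0)


class TestHeterogeneity:
    def test_null_categories_large_p(self, rng):
        n = 3000
        df = pd.DataFrame(
            {
                "driver_category": rng.choice(["a", "b"], n),
                "clnm": rng.random(n) < 0.4,
                "sex": rng.choice(["F", "M"], n),
                "age_at_ptc": rng.normal(30, 5, n),
            }
        )
        res = epi.heterogeneity_test(df)
        assert res.p > 0.05
        assert res.df == 1

    def test_real_effect_detected(self, rng):
        n = 2000
        cat = rng.choice(["a", "b"], n)
        p = np.where(cat == "a", 0.3, 0.3 * math.e / (1 - 0.3 + 0.3 * math.e))
        df = pd.DataFrame(
            {
                "driver_category": cat,
                "clnm": rng.random(n) < p,
                "sex": rng.choice(["F", "M"], n),
                "age_at_ptc": rng.normal(30, 5, n),
            }
        )
        assert epi.heterogeneity_test(df).p < 1e-4

    def test_single_category_error(self):
        df = cohort_frame(driver_category=["a"] * 10, clnm=[True] * 5 + [False] * 5)
        with pytest.raises(ValueError, match="categories"):
            epi.heterogeneity_test(df)


class TestEORModel:
    def sim(self, n, theta1, seed, baseline_odds=0.3):
        rng = np.random.default_rng(seed)
        d = np.where(rng.random(n) < 0.2, 0.0, rng.uniform(0.01, 1.0, n))
        odds = baseline_odds * (1 + theta1 * d)
        y = (rng.random(n) < odds / (1 + odds)).astype(float)
        return y, d

    def test_theta_zero_matches_plain_logistic(self, rng):
        y, d = self.sim(500, 0.0, 1)
        x = pd.DataFrame({"z": rng.normal(size=500)})
        model = ExcessOddsRatioLogit(y, x, d)
        res = model.fit(profile_ci=False)
        import statsmodels.api as sm

        logit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        theta0 = np.concatenate([np.asarray(logit.params), [0.0]])
        assert model.loglike(theta0) == pytest.approx(float(logit.llf), abs=1e-8)
        assert res.loglik >= float(logit.llf) - 1e-8

    def test_grid_oracle_agreement(self):
        """Covariate-free n=200 optimum matches a 2-D brute-force grid."""
        y, d = self.sim(200, 1.5, 3)
        model = ExcessOddsRatioLogit(y, pd.DataFrame(index=range(200)), d)
        res = model.fit(profile_ci=False)
        grid_best = max(
            model.loglike(np.array([b, t]))
            for b in np.linspace(-3, 1, 201)
            for t in np.linspace(-0.9, 8, 446)
        )
        assert res.loglik >= grid_best - 1e-4

    def test_continuity_at_theta_near_zero(self):
        """EOR loglik is continuous through theta1 = 0 (+-1e-6)."""
        y, d = self.sim(400, 0.5, 5)
        model = ExcessOddsRatioLogit(y, pd.DataFrame(index=range(400)), d)
        import statsmodels.api as sm

        logit = sm.Logit(y, np.ones((400, 1))).fit(disp=0)
        b0 = float(np.asarray(logit.params)[0])
        ll0 = float(logit.llf)
        for eps in (1e-6, -1e-6):
            assert model.loglike(np.array([b0, eps])) == pytest.approx(ll0, abs=1e-3)

    def test_lrt_invariant_to_covariate_centering(self):
        y, d = self.sim(500, 1.0, 7)
        rng = np.random.default_rng(8)
        age = rng.normal(30, 7, 500)
        res1 = epi.fit_eor(y, d, pd.DataFrame({"age": age}), profile_ci=False)
        res2 = epi.fit_eor(y, d, pd.DataFrame({"age": age - age.mean()}), profile_ci=False)
        assert res1.dose_trend_lrt().statistic == pytest.approx(
            res2.dose_trend_lrt().statistic, abs=1e-5
        )

    def test_all_doses_zero_error(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            ExcessOddsRatioLogit([0, 1], pd.DataFrame(index=range(2)), [0.0, 0.0])

    def test_positivity_constraint_respected(self):
        y, d = self.sim(300, -0.8, 11)
        res = epi.fit_eor(y, d, profile_ci=False)
        factor = 1 + res.theta1 * d
        assert (factor > 0).all()

    @pytest.mark.parametrize("terms,names", [
        ("linear", ["theta1"]),
        ("linear_quadratic", ["theta1", "theta2"]),
        ("quadratic", ["theta2"]),
    ])
    def test_dose_term_variants_fit(self, terms, names):
        y, d = self.sim(400, 1.0, 13)
        res = epi.fit_eor(y, d, dose_terms=terms, profile_ci=False)
        for nm in names:
            assert nm in res.params.index
        assert res.loglik >= res.loglik_theta0 - 1e-8

    def test_profile_ci_brackets_estimate(self):
        y, d = self.sim(2000, 1.5, 17)
        res = epi.fit_eor(y, d)
        lo, hi = res.theta1_ci
        assert lo < res.theta1 < hi

    def test_summary_renders(self):
        y, d = self.sim(300, 1.0, 19)
        text = epi.fit_eor(y, d).summary()
        assert "EOR per Gy" in text and "profile CI" in text
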