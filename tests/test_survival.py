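"""Survival statistics: KM/log-rank, Cox, power, ICC, PCA invariance."""

import numpy as np
import pandas as pd
import pytest

from petrad import (
    CohortSpec,
    CohortTable,
    PowerParams,
    cox_fit,
    icc,
    km_logrank,
    make_cohort,
    pca_invariance,
    power_sample_size,
    stepwise_multivariable,
)

from oracles import icc_anova_brute, logrank_brute


def _cohort_from(time, event, **cols):
    df = pd.DataFrame({"os_months": time, "event": event, **cols})
    df.index = [f"P{i}" for i in range(len(df))]
    return CohortTable(df)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        c = _cohort_from([1.0, 2.0, 3.0, 4.0] * 2, [1] * 8, g=[0, 0, 0, 0, 1, 1, 1, 1])
        km = km_logrank(c, c.data["g"].to_numpy())
        curve = km.curves[0]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(0.75)
        assert surv[2.0] == pytest.approx(0.5)
        assert surv[3.0] == pytest.approx(0.25)
        assert surv[4.0] == pytest.approx(0.0)

    def test_km_is_nonincreasing_from_one(self, small_cohort):
        cohort, _ = small_cohort
        g = (cohort.data["GLSZM_SzVarianc_64gl"] > 0).to_numpy()
        km = km_logrank(cohort, g)
        for c in km.curves.values():
            s = c["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_identical_groups_logrank_p_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        c = _cohort_from(np.r_[t, t], np.r_[e, e], g=[0] * 30 + [1] * 30)
        km = km_logrank(c, c.data["g"].to_numpy())
        assert km.logrank_statistic == pytest.approx(0.0, abs=1e-9)
        assert km.logrank_p == pytest.approx(1.0)

    def test_logrank_matches_hand_tabulated_oracle(self):
        rng = np.random.default_rng(5)
        t = np.round(rng.exponential(12, 60), 1) + 0.1
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60).astype(bool)
        if e.sum() == 0:
            e[0] = 1
        c = _cohort_from(t, e, g=g)
        km = km_logrank(c, g)
        assert km.logrank_statistic == pytest.approx(logrank_brute(t, e, g), rel=1e-9)

    def test_label_swap_leaves_statistic_unchanged(self, small_cohort):
        cohort, _ = small_cohort
        g = (cohort.data["GLSZM_SzVarianc_64gl"] > 0).to_numpy()
        a = km_logrank(cohort, g)
        b = km_logrank(cohort, ~g)
        assert a.logrank_statistic == pytest.approx(b.logrank_statistic)

    def test_empty_group_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            km_logrank(cohort, np.zeros(cohort.n, dtype=int))


class TestCox:
    def test_planted_binary_hazard_ratio_recovered(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0, n) / (0.03 * np.exp(np.log(2.0) * x))
        cens = np.full(n, 60.0)
        time = np.minimum(t, cens)
        event = (t <= cens).astype(int)
        c = _cohort_from(time, event, x=x)
        fit = cox_fit(c, ["x"], mode="univariate")["x"]
        hr = float(fit.hr.iloc[0])
        assert 1.8 <= hr <= 2.2
        lo, hi = float(fit.hr_ci["low"].iloc[0]), float(fit.hr_ci["high"].iloc[0])
        assert lo < 2.0 < hi

    def test_perfectly_concordant_predictor_cindex_one(self):
        t = np.arange(1.0, 41.0)
        c = _cohort_from(t, np.ones(40, int), x=-t)  # higher x = shorter survival
        fit = cox_fit(c, ["x"], mode="univariate")["x"]
        assert fit.c_index == pytest.approx(1.0)

    def test_null_covariate_p_roughly_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(21)
        ps = []
        for _ in range(60):
            n = 80
            t = rng.exponential(10, n)
            x = rng.standard_normal(n)
            c = _cohort_from(t, np.ones(n, int), x=x)
            ps.append(float(cox_fit(c, ["x"], mode="univariate")["x"].p.iloc[0]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_covariate_rejected(self, small_cohort):
        cohort, _ = small_cohort
        cohort2 = CohortTable(cohort.data.assign(const=1.0))
        with pytest.raises(ValueError, match="constant"):
            cox_fit(cohort2, ["const"])


class TestStepwise:
    def test_only_informative_candidate_retained(self):
        rng = np.random.default_rng(2)
        n = 400
        fvx = rng.standard_normal(n)
        noise1 = rng.standard_normal(n)
        noise2 = rng.standard_normal(n)
        t = rng.exponential(1.0, n) / (0.03 * np.exp(0.7 * fvx))
        cens = np.full(n, 80.0)
        c = _cohort_from(
            np.minimum(t, cens), (t <= cens).astype(int), fvx=fvx, mtv=noise1, tlg=noise2
        )
        retained, fit, history = stepwise_multivariable(c, ["fvx", "mtv", "tlg"])
        assert "fvx" in retained
        assert set(h["removed"] for h in history) <= {"mtv", "tlg"}

    def test_all_informative_retained(self):
        rng = np.random.default_rng(3)
        n = 600
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        t = rng.exponential(1.0, n) / (0.03 * np.exp(0.5 * a + 0.5 * b))
        c = _cohort_from(t, np.ones(n, int), a=a, b=b)
        retained, _, _ = stepwise_multivariable(c, ["a", "b"])
        assert set(retained) == {"a", "b"}

    def test_empty_candidates_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            stepwise_multivariable(cohort, [])


class TestPower:
    def test_study_design_inputs_reproduce_published_n(self):
        n, events = power_sample_size(PowerParams(hr=1.78))
        assert n == 203
        assert events == 84

    def test_hr_one_rejected(self):
        with pytest.raises(ValueError):
            PowerParams(hr=1.0)

    def test_monotone_in_hazard_ratio(self):
        ns = [power_sample_size(PowerParams(hr=h))[0] for h in (1.5, 1.78, 2.2, 3.0)]
        assert ns == sorted(ns, reverse=True)
        assert len(set(ns)) == len(ns)

    def test_more_power_needs_more_patients(self):
        lo = power_sample_size(PowerParams(hr=1.78, beta=0.25))[0]
        hi = power_sample_size(PowerParams(hr=1.78, beta=0.10))[0]
        assert hi > lo


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.random.default_rng(0).normal(size=(20, 1))
        r = icc(np.tile(x, (1, 3)))
        assert r.icc == pytest.approx(1.0)

    def test_variance_ratio_nine_to_one(self):
        rng = np.random.default_rng(8)
        subj = rng.normal(0, 3.0, size=(500, 1))
        ratings = subj + rng.normal(0, 1.0, size=(500, 4))
        r = icc(ratings, model="two_way_consistency")
        assert r.icc == pytest.approx(0.9, abs=0.03)

    @pytest.mark.parametrize("model", ["two_way_agreement", "two_way_consistency"])
    def test_matches_anova_table_oracle(self, model):
        rng = np.random.default_rng(13)
        for _ in range(10):
            R = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
            assert icc(R, model=model).icc == pytest.approx(icc_anova_brute(R, model), rel=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        R = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1))
        n, k = R.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": R.ravel(),
            }
        )
        tbl = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = float(tbl.loc[tbl["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        icc3 = float(tbl.loc[tbl["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert icc(R, "two_way_agreement").icc == pytest.approx(icc2, rel=1e-6)
        assert icc(R, "two_way_consistency").icc == pytest.approx(icc3, rel=1e-6)

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            icc(np.random.default_rng(0).normal(size=(10, 1)))

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            icc(np.ones((5, 3)))


class TestPCAInvariance:
    def test_single_distribution_ratio_near_one(self):
        """Between/within variance ratio concentrates near 1 under the null.

        With few scanner groups the per-cohort ratio is chi-square-ish and
        noisy, so the check averages over replicate cohorts.
        """
        ratios = [
            pca_invariance(
                make_cohort(CohortSpec(n_patients=500, seed=s))[0], "scanner_manufacturer"
            ).variance_ratio
            for s in range(8)
        ]
        assert 0.5 < np.mean(ratios) < 2.0

    def test_planted_batch_effect_detected(self):
        cohort, _ = make_cohort(CohortSpec(n_patients=300, seed=19))
        shift = (cohort.data["scanner_manufacturer"] == "Siemens").to_numpy()
        cohort.data.loc[shift, "GLSZM_SzVarianc_64gl"] += 5.0
        res = pca_invariance(cohort, "scanner_manufacturer")
        assert res.variance_ratio > 10.0

    def test_zero_variance_feature_rejected(self):
        cohort, _ = make_cohort(CohortSpec(n_patients=50, seed=23))
        cohort.data["GLSZM_SzVarianc_64gl"] = 0.0
        with pytest.raises(ValueError, match="variance"):
            pca_invariance(cohort, "scanner_manufacturer")
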