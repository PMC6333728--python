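"""Volume screening, FV scoring, LASSO-Cox discovery, dichotomisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrad import (
    CohortSpec,
    CohortTable,
    FVModel,
    FVTerm,
    dichotomise,
    feature_correlation_matrix,
    lasso_cox_discover,
    make_cohort,
    published_fvx,
    score_fv,
    select_optimal_fv,
    volume_screen_normalise,
)
from petrad.signature import FeatureVectorLassoCox, ScreenParams

from oracles import logrank_brute


def _mini_cohort(n=40, seed=0, extra=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "os_months": rng.exponential(20, n),
            "event": rng.integers(0, 2, n),
            "volume_ml": np.exp(rng.normal(3.5, 0.5, n)),
        },
        index=[f"P{i}" for i in range(n)],
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return CohortTable(df)


class TestVolumeScreen:
    def test_feature_equal_to_volume_normalises_to_one(self):
        c = _mini_cohort(extra=None)
        c.data["COPY_Vol_64gl"] = c.data["volume_ml"]
        out, report = volume_screen_normalise(c)
        assert report.loc["COPY_Vol_64gl", "normalised"]
        assert np.allclose(out.data["COPY_Vol_64gl"], 1.0)

    def test_independent_feature_untouched(self):
        rng = np.random.default_rng(3)
        c = _mini_cohort(n=200, seed=3)
        c.data["NOISE_F_64gl"] = rng.standard_normal(200)
        out, report = volume_screen_normalise(c)
        assert not report.loc["NOISE_F_64gl", "normalised"]
        assert np.array_equal(out.data["NOISE_F_64gl"], c.data["NOISE_F_64gl"])

    def test_zero_variance_feature_flagged(self):
        c = _mini_cohort()
        c.data["CONST_F_64gl"] = 1.0
        _, report = volume_screen_normalise(c)
        assert report.loc["CONST_F_64gl", "note"] == "zero variance"

    def test_too_few_patients_rejected(self):
        c = _mini_cohort(n=2)
        with pytest.raises(ValueError, match="3 patients"):
            volume_screen_normalise(c)

    def test_idempotent_once_below_threshold(self):
        c, _ = make_cohort(CohortSpec(n_patients=100, seed=9))
        c.data["VOLLIKE_F_64gl"] = c.data["volume_ml"] * np.exp(
            0.05 * np.random.default_rng(0).standard_normal(100)
        )
        once, rep1 = volume_screen_normalise(c)
        twice, rep2 = volume_screen_normalise(once)
        if not rep2["normalised"].any():
            pd.testing.assert_frame_equal(once.data, twice.data)


class TestCorrelationMatrix:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        c = _mini_cohort(n=30, extra={"A_64gl": x, "B_64gl": x, "C_64gl": -x})
        m = feature_correlation_matrix(c)
        assert m.loc["A_64gl", "B_64gl"] == pytest.approx(1.0)
        assert m.loc["A_64gl", "C_64gl"] == pytest.approx(-1.0)
        assert np.array_equal(m.values, m.values.T, equal_nan=True)

    def test_null_correlations_are_small(self):
        rng = np.random.default_rng(42)
        n = 500
        cols = {f"N{i}_64gl": rng.standard_normal(n) for i in range(8)}
        c = _mini_cohort(n=n, seed=2, extra=cols)
        m = feature_correlation_matrix(c)
        off = m.values[~np.eye(len(m), dtype=bool)]
        assert np.quantile(np.abs(off), 0.95) < 2.1 / np.sqrt(n)


class TestScoreFV:
    def test_published_weights_and_arithmetic(self):
        fvx = published_fvx()
        terms = {(t.feature, t.gray_level): t.weight for t in fvx.terms}
        assert terms == {
            ("GLSZM_SzVarianc", 64): 0.128,
            ("NGTDM_Complex", 64): -0.018,
        }
        s = score_fv(fvx, {"GLSZM_SzVarianc_64gl": 100.0, "NGTDM_Complex_64gl": 50.0})
        assert s == pytest.approx(11.9)

    def test_all_zero_features_score_zero(self):
        fvx = published_fvx()
        assert score_fv(fvx, {"GLSZM_SzVarianc_64gl": 0.0, "NGTDM_Complex_64gl": 0.0}) == 0.0

    def test_missing_term_named_in_error(self):
        with pytest.raises(KeyError, match="NGTDM_Complex_64gl"):
            score_fv(published_fvx(), {"GLSZM_SzVarianc_64gl": 1.0})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.floats(-1e3, 1e3, allow_nan=False),
        st.floats(-1e3, 1e3, allow_nan=False),
        st.floats(-10, 10, allow_nan=False),
    )
    def test_linearity(self, s, c, a):
        fvx = published_fvx()
        feats = {"GLSZM_SzVarianc_64gl": s, "NGTDM_Complex_64gl": c}
        scaled = {k: a * v for k, v in feats.items()}
        assert score_fv(fvx, scaled) == pytest.approx(a * score_fv(fvx, feats), abs=1e-6)

    def test_term_order_irrelevant(self):
        t = (FVTerm("A", 8, 2.0), FVTerm("B", 8, -1.0))
        feats = {"A_8gl": 3.0, "B_8gl": 5.0}
        assert score_fv(FVModel(t), feats) == score_fv(FVModel(t[::-1]), feats) == 1.0


class TestLassoCoxDiscovery:
    def test_planted_features_recovered_with_signs(self):
        hits = 0
        for seed in range(5):
            cohort, _ = make_cohort(CohortSpec(n_patients=300, seed=seed))
            res = lasso_cox_discover(cohort, 64, seed=seed)
            w = {t.column: t.weight for t in res.fv.terms}
            if (
                w.get("GLSZM_SzVarianc_64gl", 0) > 0
                and w.get("NGTDM_Complex_64gl", 0) < 0
            ):
                hits += 1
        assert hits >= 4

    def test_pure_noise_yields_sparse_model_at_1se(self):
        import math

        from petrad import FVModel as FV

        empties = 0
        for seed in range(5):
            spec = CohortSpec(
                n_patients=150,
                seed=100 + seed,
                true_model=FVModel(
                    (FVTerm("GLSZM_SzVarianc", 64, 0.0), FVTerm("NGTDM_Complex", 64, 0.0))
                ),
            )
            cohort, _ = make_cohort(spec)
            res = lasso_cox_discover(cohort, 64, seed=seed, penalty_rule="1se")
            empties += len(res.fv) <= 2
        assert empties >= 4

    def test_reproducible_with_fixed_seed(self, small_cohort):
        cohort, _ = small_cohort
        a = lasso_cox_discover(cohort, 64, seed=7)
        b = lasso_cox_discover(cohort, 64, seed=7)
        assert a.fv.terms == b.fv.terms
        assert a.alpha_selected == b.alpha_selected

    def test_infinite_penalty_zeroes_everything(self, small_cohort):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        cohort, _ = small_cohort
        cols = cohort.feature_columns(64)
        X = cohort.data[cols].to_numpy(float)
        Xs = (X - X.mean(0)) / X.std(0)
        y = Surv.from_arrays(
            cohort.data["event"].to_numpy(bool), cohort.data["os_months"].to_numpy(float)
        )
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e6])
        est.fit(Xs, y)
        assert np.all(est.coef_ == 0.0)

    def test_requires_events(self):
        df = pd.DataFrame(
            {
                "os_months": np.arange(1, 31, dtype=float),
                "event": 0,
                "F1_64gl": np.random.default_rng(0).standard_normal(30),
            }
        )
        with pytest.raises(ValueError, match="events"):
            FeatureVectorLassoCox(CohortTable(df), 64)


class TestSelectOptimalFV:
    def test_single_candidate_returned(self, small_cohort):
        cohort, _ = small_cohort
        fv = FVModel((FVTerm("GLSZM_SzVarianc", 64, 0.6),))
        best, table = select_optimal_fv([fv], cohort)
        assert best is fv

    def test_planted_signal_beats_noise_models(self, small_cohort):
        cohort, truth = small_cohort
        signal = FVModel(
            (FVTerm("GLSZM_SzVarianc", 64, 0.588), FVTerm("NGTDM_Complex", 64, -0.588))
        )
        noise = FVModel((FVTerm("SIM_F030", 64, 1.0),))
        best, table = select_optimal_fv([noise, signal], cohort)
        assert best is signal

    def test_tie_breaks_toward_fewer_terms(self, small_cohort):
        cohort, _ = small_cohort
        one = FVModel((FVTerm("GLSZM_SzVarianc", 64, 0.588),))
        # same score scaled: identical C-index, more terms
        two = FVModel(
            (FVTerm("GLSZM_SzVarianc", 64, 0.294), FVTerm("GLSZM_SzVarianc", 128, 0.0))
        )
        cohort.data["GLSZM_SzVarianc_128gl"] = 0.0
        best, _ = select_optimal_fv([two, one], cohort)
        assert best is one

    def test_empty_candidate_list_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="empty"):
            select_optimal_fv([], cohort)


class TestDichotomise:
    def test_median_split(self):
        d = dichotomise(np.array([1.0, 2.0, 3.0, 4.0]), method="median")
        assert list(d.high_risk) == [False, False, True, True]

    def test_median_ties_go_low(self):
        d = dichotomise(np.array([1.0, 2.0, 2.0, 4.0]), method="median")
        assert list(d.high_risk) == [False, False, False, True]

    def test_youden_perfect_separation(self, small_cohort):
        cohort, _ = small_cohort
        time = cohort.data["os_months"].to_numpy()
        med = np.median(time)
        # a score that exactly predicts short survival
        scores = (time <= med).astype(float)
        d = dichotomise(scores, method="youden", cohort=cohort)
        assert d.details["youden_j"] == pytest.approx(1.0)

    def test_optimal_logrank_beats_median_statistic(self, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(cohort.n)
        time = cohort.data["os_months"].to_numpy()
        event = cohort.data["event"].to_numpy()
        d = dichotomise(scores, method="optimal_logrank", cohort=cohort)
        stat_med = logrank_brute(time, event, scores > np.median(scores))
        assert d.details["statistic"] >= stat_med - 1e-9

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomise(np.ones(10), method="median")
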