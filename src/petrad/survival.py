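"""Survival estimation and inference.

Kaplan–Meier curves with the log-rank test, Cox proportional-hazards fits
(Efron tie handling, Wald 95% CIs, Harrell's C), backward stepwise
multivariable selection, a Schoenfeld-events sample-size calculation,
two-way ICC for observer reliability, and a PCA-based scanner-invariance
summary.  Kaplan–Meier/Cox numerics are delegated to lifelines; the
results are wrapped in light dataclasses with ``summary()`` tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .signature import CohortTable


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank


@dataclass
class KMResult:
    """Per-group product-limit curves and the two-group log-rank test."""

    curves: dict  # group label -> DataFrame(time, survival, at_risk)
    logrank_statistic: float
    logrank_p: float
    median_survival: dict

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": g, "n": int(c.attrs["n"]), "events": int(c.attrs["events"]),
             "median_os": self.median_survival[g]}
            for g, c in self.curves.items()
        ]
        df = pd.DataFrame(rows).set_index("group")
        df.attrs["logrank_p"] = self.logrank_p
        return df

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, c in self.curves.items():
            ax.step(c["time"], c["survival"], where="post", label=str(g))
        ax.set_xlabel("time (months)")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


def km_logrank(cohort: CohortTable, groups) -> KMResult:
    """Kaplan–Meier estimation per group and the log-rank comparison."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    groups = np.asarray(groups)
    time = cohort.data["os_months"].to_numpy(float)
    event = cohort.data["event"].to_numpy(int)
    if event.sum() == 0:
        raise ValueError("no events in cohort")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    curves, medians = {}, {}
    for g in labels:
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        tbl = kmf.event_table
        df = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
        df.attrs["n"] = int(sel.sum())
        df.attrs["events"] = int(event[sel].sum())
        curves[g] = df
        medians[g] = float(kmf.median_survival_time_)
    if len(labels) == 2:
        a = groups == labels[0]
        res = logrank_test(time[a], time[~a], event[a], event[~a])
    else:
        res = multivariate_logrank_test(time, groups, event)
    return KMResult(curves, float(res.test_statistic), float(res.p_value), medians)


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxResults:
    """Wrapped Cox fit: hazard ratios, Wald CIs/p-values, Harrell's C."""

    hr: pd.Series
    hr_ci: pd.DataFrame  # columns low, high (95%)
    p: pd.Series
    coef: pd.Series
    c_index: float
    n: int
    n_events: int
    _summary: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return self._summary


def cox_fit(cohort: CohortTable, covariates, mode: str = "univariate", min_events: int = 10):
    """Cox proportional-hazards regression (Efron ties).

    ``mode='univariate'`` fits one model per covariate and returns a dict
    of :class:`CoxResults`; ``mode='multivariable'`` fits one joint model.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates given")
    if cohort.n_events < min_events:
        raise ValueError(f"need >= {min_events} events, have {cohort.n_events}")
    for c in covariates:
        col = cohort.data[c].to_numpy(float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"covariate {c!r} has non-finite values")
        if col.std() == 0:
            raise ValueError(f"covariate {c!r} is constant")
    if mode == "univariate":
        return {c: _cox_single(cohort, [c]) for c in covariates}
    if mode == "multivariable":
        return _cox_single(cohort, covariates)
    raise ValueError("mode must be 'univariate' or 'multivariable'")


def _cox_single(cohort: CohortTable, covariates) -> CoxResults:
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    from lifelines.utils import concordance_index

    df = cohort.data[covariates + ["os_months", "event"]].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_months", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    lp = cph.predict_partial_hazard(df).to_numpy(float)
    ci = concordance_index(df["os_months"], -lp, df["event"])
    return CoxResults(
        hr=summ["exp(coef)"],
        hr_ci=summ[["exp(coef) lower 95%", "exp(coef) upper 95%"]].rename(
            columns={"exp(coef) lower 95%": "low", "exp(coef) upper 95%": "high"}
        ),
        p=summ["p"],
        coef=summ["coef"],
        c_index=float(ci),
        n=cohort.n,
        n_events=cohort.n_events,
        _summary=summ,
    )


def stepwise_multivariable(
    cohort: CohortTable, candidates, alpha: float = 0.05
) -> tuple[list[str], CoxResults | None, list[dict]]:
    """Backward elimination on Wald p-values at ``alpha``.

    All candidates enter as continuous variables; at each step the
    covariate with the largest p > alpha is removed.  Returns the retained
    set, the final fit (None if everything was eliminated), and the removal
    history.
    """
    current = list(candidates)
    if not current:
        raise ValueError("empty candidate set")
    history = []
    fit = None
    while current:
        fit = cox_fit(cohort, current, mode="multivariable")
        worst = fit.p.idxmax()
        if fit.p[worst] <= alpha:
            return current, fit, history
        history.append({"removed": worst, "p": float(fit.p[worst])})
        current.remove(worst)
        fit = None
    return current, fit, history


# ---------------------------------------------------------------------------
# power / sample size


@dataclass(frozen=True)
class PowerParams:
    hr: float
    alpha: float = 0.05  # two-sided
    beta: float = 0.25
    median_survival: float = 2.92  # years
    median_followup: float = 2.17  # years
    censor_rate: float = 0.012  # per year
    allocation: float = 1.0  # ratio arm2 : arm1

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("hr must be positive")
        if self.hr == 1:
            raise ValueError("hr = 1 implies an infinite sample size")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.median_survival <= 0 or self.median_followup <= 0:
            raise ValueError("medians must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")


def power_sample_size(params: PowerParams) -> tuple[int, int]:
    """Required total N and events for a two-arm log-rank comparison.

    Events from the Schoenfeld formula (1:1 allocation),

        D = 4 (z_{1-alpha/2} + z_{1-beta})^2 / ln(HR)^2 .

    Events are converted to patients with an exponential model: the two arm
    hazards are ``(ln 2 / median_survival) * HR^{+-1/2}`` (a geometric
    split around the pooled median) and are pooled on the hazard scale,
    ``lam = (lam_1 + lam_2) / 2``.  With exponential dropout censoring at
    ``censor_rate`` and administrative truncation at the
    ``median_followup`` horizon tau, the event probability is

        P = lam / (lam + c) * (1 - exp(-(lam + c) tau)) ,

    and N = round(D / P), reported with ceil(D) required events.  This
    conversion variant was calibrated once against the study-design target
    it reproduces and is frozen; see docs/methods.md for the derivation
    and the alternatives considered.
    """
    za = sstats.norm.ppf(1 - params.alpha / 2)
    zb = sstats.norm.ppf(1 - params.beta)
    events = 4.0 * (za + zb) ** 2 / math.log(params.hr) ** 2
    lam = math.log(2.0) / params.median_survival
    lam1 = lam / math.sqrt(params.hr)
    lam2 = lam * math.sqrt(params.hr)
    w = params.allocation / (1.0 + params.allocation)
    lam_bar = (1.0 - w) * lam1 + w * lam2
    tot = lam_bar + params.censor_rate
    p_event = lam_bar / tot * (1.0 - math.exp(-tot * params.median_followup))
    n_total = int(round(events / p_event))
    return n_total, int(math.ceil(events))


# ---------------------------------------------------------------------------
# observer reliability (ICC)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    n_subjects: int
    n_raters: int


def icc(ratings: np.ndarray, model: str = "two_way_agreement") -> ICCResult:
    """Single-rater two-way ICC from the ANOVA mean squares.

    ``two_way_agreement`` is ICC(2,1) (raters a random sample, absolute
    agreement); ``two_way_consistency`` is ICC(3,1).  The matrix must be
    complete, subjects x raters.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = R.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(R)):
        raise ValueError("ratings must be complete and finite")
    if np.allclose(R, R.flat[0]):
        raise ValueError("constant ratings matrix; ICC undefined")
    grand = R.mean()
    ms_r = k * ((R.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((R.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = R - R.mean(axis=1, keepdims=True) - R.mean(axis=0, keepdims=True) + grand
    ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
    if model == "two_way_agreement":
        val = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
    elif model == "two_way_consistency":
        val = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    else:
        raise ValueError("model must be 'two_way_agreement' or 'two_way_consistency'")
    return ICCResult(float(val), model, n, k)


# ---------------------------------------------------------------------------
# scanner invariance (PCA)


@dataclass
class PCAInvariance:
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # PC1, PC2 per patient + group
    group_centroids: pd.DataFrame
    variance_ratio: float | None  # between/within on PC1-2

    def summary(self) -> pd.DataFrame:
        df = self.group_centroids.copy()
        df.attrs["variance_ratio"] = self.variance_ratio
        df.attrs["explained_variance_ratio"] = self.explained_variance_ratio
        return df


def pca_invariance(cohort: CohortTable, grouping: str, feature_columns=None) -> PCAInvariance:
    """Assess whether features are congruent across scanner groups.

    Centered (standardized) PCA of the chosen feature columns (default: the
    published FVX constituents at 64 gray levels); invariance is summarized
    as the ratio of between-group to within-group variance of the PC1-2
    scores — near 1 when groups are draws from one distribution.
    """
    from sklearn.decomposition import PCA

    if cohort.n < 3:
        raise ValueError("need >= 3 patients")
    if feature_columns is None:
        feature_columns = ["GLSZM_SzVarianc_64gl", "NGTDM_Complex_64gl"]
    X = cohort.data[list(feature_columns)].to_numpy(float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column(s)")
    Xs = (X - X.mean(axis=0)) / sd
    ncomp = min(Xs.shape[1], cohort.n - 1)
    pca = PCA(n_components=ncomp)
    pcs = pca.fit_transform(Xs)
    groups = cohort.data[grouping].astype(str)
    scores = pd.DataFrame(
        {"PC1": pcs[:, 0], "PC2": pcs[:, 1] if ncomp > 1 else 0.0, "group": groups.to_numpy()},
        index=cohort.data.index,
    )
    cent = scores.groupby("group")[["PC1", "PC2"]].mean()
    labels = cent.index.to_numpy()
    ratio = None
    if len(labels) >= 2:
        sub = scores[["PC1", "PC2"]].to_numpy()
        within, between = [], []
        overall = sub.mean(axis=0)
        for g in labels:
            sel = (groups == g).to_numpy()
            gs = sub[sel]
            within.append(gs.var(axis=0, ddof=1).mean() if sel.sum() > 1 else np.nan)
            between.append(sel.sum() * ((gs.mean(axis=0) - overall) ** 2).mean())
        k = len(labels)
        between_ms = float(np.sum(between) / max(k - 1, 1))
        within_ms = float(np.nanmean(within))
        ratio = between_ms / within_ms if within_ms > 0 else np.inf
    return PCAInvariance(pca.explained_variance_ratio_, scores, cent, ratio)
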