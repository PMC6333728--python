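"""Prognostic feature-vector discovery and scoring.

A *feature vector* (FV) is a sparse weighted linear combination of radiomics
features at one gray level, discovered with an L1-penalized Cox model on a
training cohort.  The published lung-cancer classifier FVX,

    FVX = 0.128 * GLSZM_SzVarianc_64gl - 0.018 * NGTDM_Complex_64gl,

ships with the package (``data/fvx_published.json``) and is scored by
:func:`score_fv`.

Discovery follows the statsmodels convention: build a
:class:`FeatureVectorLassoCox` model from a cohort, call ``fit`` and obtain
a results object carrying the selected terms, the regularization path, the
cross-validated deviance curve and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

RESERVED_COLUMNS = frozenset(
    {
        "patient_id", "os_months", "event", "stage", "volume_ml",
        "suv_max", "suv_mean", "suv_peak", "mtv_ml", "tlg",
        "scanner_manufacturer", "scanner_model", "slice_thickness",
        "matrix_rows", "matrix_cols",
    }
)


@dataclass
class CohortTable:
    """Per-patient features plus survival and clinical columns.

    ``data`` is indexed by patient id; feature columns are every column not
    in :data:`RESERVED_COLUMNS` and are named ``<Family>_<Feature>_<G>gl``.
    Requires ``os_months`` (>= 0) and ``event`` (0/1, death = 1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("os_months", "event"):
            if col not in df.columns:
                raise ValueError(f"cohort lacks required column {col!r}")
        if df.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        if (df["os_months"] < 0).any():
            raise ValueError("os_months must be >= 0")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event flag must be 0/1")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def feature_columns(self, gray_level: int | None = None) -> list[str]:
        cols = [c for c in self.data.columns if c not in RESERVED_COLUMNS]
        if gray_level is not None:
            suffix = f"_{gray_level}gl"
            cols = [c for c in cols if c.endswith(suffix)]
        return cols


# ---------------------------------------------------------------------------
# feature vectors


@dataclass(frozen=True)
class FVTerm:
    feature: str
    gray_level: int
    weight: float

    @property
    def column(self) -> str:
        return f"{self.feature}_{self.gray_level}gl"


@dataclass
class FVModel:
    """A discovered or published feature vector."""

    terms: tuple[FVTerm, ...]
    provenance: str = "discovered"

    def __post_init__(self) -> None:
        cols = [t.column for t in self.terms]
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate features in feature vector")
        self.terms = tuple(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def to_json(self, path=None) -> str:
        payload = {
            "terms": [
                {"feature": t.feature, "gray_level": t.gray_level, "weight": t.weight}
                for t in self.terms
            ],
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FVModel":
        if isinstance(source, (dict,)):
            payload = source
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        terms = tuple(
            FVTerm(t["feature"], int(t["gray_level"]), float(t["weight"]))
            for t in payload["terms"]
        )
        return cls(terms, payload.get("provenance", "discovered"))


def published_fvx() -> FVModel:
    """The published FVX classifier with its frozen weights."""
    text = resources.files("petrad.data").joinpath("fvx_published.json").read_text()
    return FVModel.from_json(text)


def score_fv(model: FVModel, features) -> float | pd.Series:
    """Linear FV score: sum of weight x feature value.

    ``features`` may be a mapping/Series of full feature names, a DataFrame
    (one row per patient; returns a Series), or a list of per-gray-level
    FeatureSets for one tumor.
    """
    if isinstance(features, list):  # FeatureSets
        merged: dict[str, float] = {}
        for fs in features:
            merged.update(fs.values)
        features = merged
    if isinstance(features, pd.DataFrame):
        for t in model.terms:
            if t.column not in features.columns:
                raise KeyError(f"feature {t.column!r} missing from table")
        return sum(t.weight * features[t.column] for t in model.terms)
    score = 0.0
    for t in model.terms:
        if t.column not in features:
            raise KeyError(f"feature {t.column!r} missing")
        val = features[t.column]
        if isinstance(val, float) and np.isnan(val):
            raise KeyError(f"feature {t.column!r} is missing (NaN)")
        score += t.weight * val
    return score


# ---------------------------------------------------------------------------
# volume screening


@dataclass(frozen=True)
class ScreenParams:
    volume_corr_threshold: float = 0.7

    def __post_init__(self) -> None:
        if not (0 < self.volume_corr_threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")


def volume_screen_normalise(
    cohort: CohortTable, params: ScreenParams | None = None
) -> tuple[CohortTable, pd.DataFrame]:
    """Divide volume-confounded features by tumor volume.

    For each feature the Spearman rank correlation with ``volume_ml`` is
    computed across patients; features with |rho| >= the threshold are
    replaced by feature / volume.  Returns the transformed cohort and a
    report listing every feature with its rho and whether it was normalised.
    Zero-variance features (rho undefined) are left untouched and flagged.
    """
    params = params or ScreenParams()
    if cohort.n < 3:
        raise ValueError("need at least 3 patients for rank correlation")
    if "volume_ml" not in cohort.data.columns:
        raise ValueError("cohort lacks volume_ml")
    vol = cohort.data["volume_ml"].to_numpy(dtype=float)
    if (vol <= 0).any():
        raise ValueError("volume_ml must be positive")
    df = cohort.data.copy()
    rows = []
    for col in cohort.feature_columns():
        x = df[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append({"feature": col, "rho": np.nan, "normalised": False, "note": "zero variance"})
            continue
        rho = stats.spearmanr(x, vol).statistic
        normalise = np.isfinite(rho) and abs(rho) >= params.volume_corr_threshold
        if normalise:
            df[col] = x / vol
        rows.append({"feature": col, "rho": rho, "normalised": bool(normalise), "note": ""})
    report = pd.DataFrame(rows).set_index("feature")
    return CohortTable(df), report


def feature_correlation_matrix(cohort: CohortTable, columns=None) -> pd.DataFrame:
    """Pairwise Spearman correlation of feature columns (heatmap input).

    Constant features yield NaN rows/columns; the diagonal is 1 elsewhere.
    """
    if cohort.n < 3:
        raise ValueError("need at least 3 patients")
    cols = list(columns) if columns is not None else cohort.feature_columns()
    sub = cohort.data[cols].astype(float)
    corr = sub.corr(method="spearman")
    const = sub.nunique() <= 1
    corr.loc[const, :] = np.nan
    corr.loc[:, const] = np.nan
    np.fill_diagonal(corr.values, np.where(const, np.nan, 1.0))
    return corr


# ---------------------------------------------------------------------------
# LASSO-Cox discovery (Model / Results)


def _log_partial_likelihood(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a fixed linear predictor."""
    order = np.argsort(-time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    # cumulative log-sum-exp over the risk set (times sorted descending)
    m = lp.max()
    csum = np.cumsum(np.exp(lp - m))
    # handle ties: risk set includes all with t_j >= t_i
    risk = np.log(csum) + m
    # tied times share one risk set: use the last index of each time block
    block_end = np.empty(len(time), dtype=int)
    j = len(time) - 1
    for i in range(len(time) - 1, -1, -1):
        if i == len(time) - 1 or time[i] != time[i + 1]:
            j = i
        block_end[i] = j
    ev = event.astype(bool)
    return float((lp[ev] - risk[block_end[ev]]).sum())


class FeatureVectorLassoCox:
    """L1-penalized Cox discovery of a feature vector at one gray level.

    Features are standardized internally (zero mean, unit variance); the
    reported weights are back-transformed to the original feature scale.
    The penalty is chosen by K-fold cross-validated partial-likelihood
    deviance, with both the minimum-deviance and 1-SE rules available
    (default: minimum).
    """

    def __init__(
        self,
        cohort: CohortTable,
        gray_level: int,
        cv_folds: int = 10,
        penalty_rule: str = "min",
        feature_columns=None,
        min_events: int = 20,
    ) -> None:
        if penalty_rule not in ("min", "1se"):
            raise ValueError("penalty_rule must be 'min' or '1se'")
        self.cohort = cohort
        self.gray_level = int(gray_level)
        self.cv_folds = int(cv_folds)
        self.penalty_rule = penalty_rule
        self.min_events = min_events
        self.columns = (
            list(feature_columns)
            if feature_columns is not None
            else cohort.feature_columns(gray_level)
        )
        if not self.columns:
            raise ValueError(f"no features at gray level {gray_level}")
        if cohort.n_events == 0:
            raise ValueError("cohort has no events")
        if cohort.n_events < min_events:
            raise ValueError(
                f"need >= {min_events} events for stable discovery, "
                f"have {cohort.n_events}"
            )

    def fit(self, seed: int = 0) -> "FeatureVectorLassoCoxResults":
        from sklearn.model_selection import KFold
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        df = self.cohort.data
        X = df[self.columns].to_numpy(dtype=float)
        keep = X.std(axis=0) > 0
        cols = [c for c, k in zip(self.columns, keep) if k]
        X = X[:, keep]
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Xs = (X - mu) / sd
        y = Surv.from_arrays(
            event=df["event"].to_numpy(bool), time=df["os_months"].to_numpy(float)
        )
        time = df["os_months"].to_numpy(float)
        event = df["event"].to_numpy(float)

        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=60)
        path.fit(Xs, y)
        alphas = np.asarray(path.alphas_)

        kf = KFold(n_splits=self.cv_folds, shuffle=True, random_state=seed)
        fold_dev = np.full((self.cv_folds, len(alphas)), np.nan)
        for f, (tr, te) in enumerate(kf.split(Xs)):
            if event[te].sum() == 0 or event[tr].sum() == 0:
                continue
            est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xs[tr], y[tr])
            coefs = est.coef_  # (n_features, n_alphas_fitted)
            fitted = np.asarray(est.alphas_)
            for a_idx, alpha in enumerate(alphas):
                j = int(np.argmin(np.abs(fitted - alpha)))
                lp = Xs[te] @ coefs[:, j]
                fold_dev[f, a_idx] = -2.0 * _log_partial_likelihood(lp, time[te], event[te])
        mean_dev = np.nanmean(fold_dev, axis=0)
        se_dev = np.nanstd(fold_dev, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(fold_dev), axis=0).clip(min=1)
        )
        i_min = int(np.nanargmin(mean_dev))
        if self.penalty_rule == "1se":
            bound = mean_dev[i_min] + se_dev[i_min]
            ok = np.nonzero(mean_dev <= bound)[0]
            # alphas_ are sorted decreasing: the first qualifying index is
            # the strongest penalty within one SE
            i_sel = int(ok[0]) if ok.size else i_min
        else:
            i_sel = i_min
        alpha_sel = float(alphas[i_sel])

        final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        final.fit(Xs, y)
        j = int(np.argmin(np.abs(np.asarray(final.alphas_) - alpha_sel)))
        w_std = final.coef_[:, j]
        nz = np.nonzero(w_std != 0.0)[0]
        terms = tuple(
            FVTerm(
                cols[k].removesuffix(f"_{self.gray_level}gl"),
                self.gray_level,
                float(w_std[k] / sd[k]),
            )
            for k in nz
        )
        if not terms:
            warnings.warn("all weights zero at the selected penalty; empty model", stacklevel=2)
        fv = FVModel(terms, provenance="discovered")
        return FeatureVectorLassoCoxResults(
            model=self,
            fv=fv,
            alphas=alphas,
            cv_deviance=mean_dev,
            cv_deviance_se=se_dev,
            alpha_selected=alpha_sel,
            coef_path=final.coef_,
            standardization=(cols, mu, sd),
        )


@dataclass
class FeatureVectorLassoCoxResults:
    """Fitted feature-vector discovery: selected terms, path, CV curve."""

    model: FeatureVectorLassoCox
    fv: FVModel
    alphas: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    alpha_selected: float
    coef_path: np.ndarray
    standardization: tuple

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "feature": t.feature,
                "gray_level": t.gray_level,
                "weight": t.weight,
            }
            for t in self.fv.terms
        ]
        return pd.DataFrame(rows)

    def plot_cv_curve(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(np.log(self.alphas), self.cv_deviance, yerr=self.cv_deviance_se, fmt="o-")
        ax.axvline(np.log(self.alpha_selected), ls="--", color="k")
        ax.set_xlabel("log penalty")
        ax.set_ylabel("CV partial-likelihood deviance")
        return ax


def lasso_cox_discover(
    cohort: CohortTable,
    gray_level: int,
    cv_folds: int = 10,
    seed: int = 0,
    penalty_rule: str = "min",
) -> FeatureVectorLassoCoxResults:
    """Functional wrapper around :class:`FeatureVectorLassoCox`."""
    return FeatureVectorLassoCox(
        cohort, gray_level, cv_folds=cv_folds, penalty_rule=penalty_rule
    ).fit(seed=seed)


# ---------------------------------------------------------------------------
# model selection across gray levels


def cross_validated_cindex(
    fv: FVModel, cohort: CohortTable, cv_folds: int = 10, seed: int = 0
) -> float:
    """Mean held-out Harrell C of the (fixed-weight) FV score."""
    from lifelines.utils import concordance_index
    from sklearn.model_selection import KFold

    if len(fv) == 0:
        return 0.5
    scores = score_fv(fv, cohort.data).to_numpy(dtype=float)
    time = cohort.data["os_months"].to_numpy(float)
    event = cohort.data["event"].to_numpy(int)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cis = []
    for _, te in kf.split(scores):
        if event[te].sum() == 0:
            continue
        # higher FV score = higher risk, so concordance is against -score
        cis.append(concordance_index(time[te], -scores[te], event[te]))
    return float(np.mean(cis))


def select_optimal_fv(
    models: list[FVModel], cohort: CohortTable, cv_folds: int = 10, seed: int = 0
) -> tuple[FVModel, pd.DataFrame]:
    """Rank candidate FVs by cross-validated C-index on the training cohort.

    Ties break toward fewer terms, then the lower maximum gray level.
    Returns the winner and the ranking table.
    """
    if not models:
        raise ValueError("empty candidate list")
    rows = []
    for k, fv in enumerate(models):
        ci = cross_validated_cindex(fv, cohort, cv_folds=cv_folds, seed=seed)
        gmax = max((t.gray_level for t in fv.terms), default=0)
        rows.append({"candidate": k, "c_index": ci, "n_terms": len(fv), "gray_level": gmax})
    table = pd.DataFrame(rows).set_index("candidate")
    ranked = table.sort_values(
        by=["c_index", "n_terms", "gray_level"], ascending=[False, True, True], kind="stable"
    )
    best = models[int(ranked.index[0])]
    return best, ranked


# ---------------------------------------------------------------------------
# dichotomisation


@dataclass
class Dichotomy:
    high_risk: np.ndarray  # boolean, True = high-score group
    cutoff: float
    method: str
    details: dict = field(default_factory=dict)


def dichotomise(
    scores, method: str = "median", cohort: CohortTable | None = None, min_group_frac: float = 0.10
) -> Dichotomy:
    """Split continuous scores into binary risk groups.

    ``median``: split at the sample median, scores equal to the median go
    to the low-score group.  ``youden``: cutoff maximizing Youden's J on
    the ROC against the binary outcome 'survived beyond the cohort median
    OS' (patients censored before the median are not evaluable).
    ``optimal_logrank``: cutoff maximizing the two-group log-rank statistic
    over interior candidate splits with both groups >= ``min_group_frac``
    of the cohort.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 patients")
    if np.all(scores == scores[0]):
        raise ValueError("all scores identical; no split exists")

    if method == "median":
        cut = float(np.median(scores))
        return Dichotomy(scores > cut, cut, method)

    if cohort is None:
        raise ValueError(f"method {method!r} requires a cohort")
    time = cohort.data["os_months"].to_numpy(float)
    event = cohort.data["event"].to_numpy(int)

    if method == "youden":
        med_os = float(np.median(time))
        evaluable = (time > med_os) | ((event == 1) & (time <= med_os))
        if evaluable.sum() < 2:
            raise ValueError("too few evaluable patients for the median-survival label")
        label_short = ((time <= med_os) & (event == 1))[evaluable]
        sc = scores[evaluable]
        if label_short.all() or (~label_short).all():
            raise ValueError("median-survival label is constant")
        from sklearn.metrics import roc_curve

        fpr, tpr, thr = roc_curve(label_short.astype(int), sc)
        j = tpr - fpr
        k = int(np.argmax(j))
        cut = float(thr[k])
        return Dichotomy(
            scores >= cut, cut, method, details={"youden_j": float(j[k]), "median_os": med_os}
        )

    if method == "optimal_logrank":
        from lifelines.statistics import logrank_test

        n = scores.size
        floor = max(1, int(np.ceil(min_group_frac * n)))
        order = np.sort(np.unique(scores))
        best = None
        for cut in order[:-1]:
            hi = scores > cut
            if hi.sum() < floor or (~hi).sum() < floor:
                continue
            res = logrank_test(time[hi], time[~hi], event[hi], event[~hi])
            stat = float(res.test_statistic)
            if best is None or stat > best[1]:
                best = (float(cut), stat, float(res.p_value))
        if best is None:
            raise ValueError("no candidate split satisfies the group-size floor")
        cut, stat, p = best
        return Dichotomy(scores > cut, cut, method, details={"statistic": stat, "p_value": p})

    raise ValueError(f"unknown method {method!r}")
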