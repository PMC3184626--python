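"""Descriptive comparison and logistic models for discontinuation of employment.

The binary outcome pools temporary and indefinite discontinuation "because of
fatigue-related symptoms" against current employment; "other" and unrecorded
statuses are excluded from the comparison. Continuous inventories enter the
models rescaled to a common 0-10 range, age as a linear per-decade term (band
midpoint / 10) and duration of illness in years; every model additionally
adjusts for centre and year of assessment as unordered categorical indicators.

The logistic fit is maximum likelihood by iteratively reweighted least squares
(Newton scoring), converged when the largest absolute coefficient change
drops below 1e-8 (at most 100 iterations), with Wald 95% confidence intervals
exponentiated onto the odds-ratio scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort, scores

#: The eight patient characteristics of the association analysis, in order.
DEFAULT_COVARIATES = (
    "age_decade",
    "female",
    "duration_years",
    "chalder",
    "sf36_pf",
    "hads_anxiety",
    "hads_depression",
    "vas_pain",
)
DEFAULT_ADJUSTMENT = ("centre", "assessment_year")

CONTINUOUS_VARIABLES = (
    "duration_illness",
    "chalder_total",
    "sf36pf_total",
    "hads_anxiety",
    "hads_depression",
    "vas_pain",
)


class SeparationWarning(UserWarning):
    """Raised-as-warning diagnostic for (quasi-)complete separation."""


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model on the discontinued-vs-employed outcome."""

    params: pd.Series
    bse: pd.Series
    n: int
    converged: bool
    loglik: float
    loglik_path: tuple[float, ...]
    specification: tuple[str, ...]

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def conf_int(self) -> pd.DataFrame:
        lo = np.exp(self.params - 1.96 * self.bse)
        hi = np.exp(self.params + 1.96 * self.bse)
        return pd.DataFrame({"or_low": lo, "or_high": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "odds_ratio": self.odds_ratios,
                "p_value": self.pvalues,
            }
        )
        return out.join(self.conf_int)


@dataclass(frozen=True)
class AssociationTest:
    statistic: float
    df: float
    p_value: float
    method: str


@dataclass(frozen=True)
class GroupSummary:
    """Table-1-style comparison of employed vs discontinued groups."""

    n_employed: int
    n_discontinued: int
    continuous: pd.DataFrame
    categorical: pd.DataFrame


# ---------------------------------------------------------------------------
# outcome and design construction


def resolve_outcome(frame: pd.DataFrame) -> pd.Series:
    """1 = discontinued (temporary or indefinite), 0 = employed, NaN otherwise."""
    status = frame["employment_status"]
    out = pd.Series(np.nan, index=frame.index)
    out[status == "currently_employed"] = 0.0
    out[status.isin(cohort.DISCONTINUED_STATUSES)] = 1.0
    return out


def covariate_frame(scored: pd.DataFrame) -> pd.DataFrame:
    """Model covariates on their regression scales (NaN propagates)."""
    bands = cohort.age_band_series(scored["age"])
    mid = bands.map(cohort.AGE_BAND_MIDPOINTS).astype(float)
    return pd.DataFrame(
        {
            "age_decade": mid / 10.0,
            "female": (scored["sex"] == "female").astype(float),
            "duration_years": scored["duration_illness"] / 12.0,
            "chalder": scores.rescale_for_regression(scored["chalder_total"], 33),
            "sf36_pf": scores.rescale_for_regression(scored["sf36pf_total"], 100),
            "hads_anxiety": scores.rescale_for_regression(scored["hads_anxiety"], 21),
            "hads_depression": scores.rescale_for_regression(
                scored["hads_depression"], 21
            ),
            "vas_pain": scores.rescale_for_regression(scored["vas_pain"], 100),
        },
        index=scored.index,
    )


def _adjustment_dummies(scored: pd.DataFrame, adjust: Sequence[str]) -> pd.DataFrame:
    parts = []
    for col in adjust:
        cats = scored[col].astype(str)
        levels = sorted(cats.unique())
        for level in levels[1:]:  # reference = first level alphabetically
            parts.append((f"{col}[{level}]", (cats == level).astype(float)))
    if not parts:
        return pd.DataFrame(index=scored.index)
    return pd.DataFrame(dict(parts), index=scored.index)


def build_design(
    scored: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    adjust: Sequence[str] = DEFAULT_ADJUSTMENT,
    complete_on: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Complete-case design matrix (with intercept) and 0/1 outcome.

    ``complete_on`` restricts to records complete for those covariates (in
    addition to the outcome); it defaults to the fitted covariates, but the
    published analysis fixes one complete-case set across all models, so the
    partially adjusted fits pass the full covariate list here.
    """
    y = resolve_outcome(scored)
    X = covariate_frame(scored)[list(covariates)]
    need = covariate_frame(scored)[list(complete_on or covariates)]
    keep = y.notna() & need.notna().all(axis=1)
    X = X.loc[keep]
    dummies = _adjustment_dummies(scored.loc[keep], adjust)
    design = pd.concat([pd.Series(1.0, index=X.index, name="intercept"), X, dummies], axis=1)
    return design, y.loc[keep]


# ---------------------------------------------------------------------------
# IRLS logistic regression


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        collinear = [names[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def fit_logistic(
    X: pd.DataFrame,
    y: pd.Series,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a logistic regression by IRLS on an explicit design matrix.

    The design must already contain its intercept column. Separation is
    flagged (``converged=False`` plus a :class:`SeparationWarning`), never
    silently reported; a rank-deficient design raises, naming the collinear
    columns.
    """
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    ym = np.asarray(y, dtype=float)
    if set(np.unique(ym)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    _check_rank(Xm, names)

    beta = np.zeros(Xm.shape[1])
    path: list[float] = []
    converged = False
    for _ in range(max_iter):
        eta = Xm @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        path.append(float(np.sum(ym * np.log(mu) + (1 - ym) * np.log(1 - mu))))
        w = mu * (1 - mu)
        z = eta + (ym - mu) / w
        xtw = Xm.T * w
        beta_new = np.linalg.solve(xtw @ Xm, xtw @ z)
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = Xm @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    path.append(float(np.sum(ym * np.log(mu) + (1 - ym) * np.log(1 - mu))))
    if not converged or np.max(np.abs(beta)) > 30:
        converged = False
        warnings.warn(
            "logistic fit did not converge cleanly — likely complete or "
            "quasi-complete separation; inspect the design",
            SeparationWarning,
            stacklevel=2,
        )
    cov = np.linalg.inv((Xm.T * (mu * (1 - mu))) @ Xm)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        n=len(ym),
        converged=converged,
        loglik=path[-1],
        loglik_path=tuple(path),
        specification=tuple(names),
    )


def fit_employment_model(
    scored: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    adjust: Sequence[str] = DEFAULT_ADJUSTMENT,
    complete_on: Sequence[str] | None = None,
) -> LogisticFit:
    """Build the design from a scored cohort and fit it."""
    X, y = build_design(scored, covariates, adjust, complete_on)
    return fit_logistic(X, y)


def partially_adjusted_models(
    scored: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    adjust: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> dict[str, LogisticFit]:
    """One centre/year-adjusted model per covariate, all on the shared
    complete-case set (complete for every covariate in ``covariates``)."""
    return {
        cov: fit_employment_model(scored, (cov,), adjust, complete_on=covariates)
        for cov in covariates
    }


def fully_adjusted_model(
    scored: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    adjust: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> LogisticFit:
    """The joint model with all eight characteristics plus centre/year."""
    return fit_employment_model(scored, covariates, adjust)


# ---------------------------------------------------------------------------
# descriptive comparison and association tests


def summarize_by_employment(scored: pd.DataFrame) -> GroupSummary:
    """Median (IQR) per continuous variable and counts/row-percentages for
    sex and age band, split by employment group, on available cases."""
    y = resolve_outcome(scored)
    groups = {"employed": scored[y == 0], "discontinued": scored[y == 1]}

    cont_rows = []
    for var in CONTINUOUS_VARIABLES:
        row: dict[str, float] = {"variable": var}
        for gname, g in groups.items():
            vals = g[var].dropna()
            row[f"n_{gname}"] = len(vals)
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            row[f"median_{gname}"] = med
            row[f"q1_{gname}"] = q1
            row[f"q3_{gname}"] = q3
        cont_rows.append(row)

    cat_rows = []
    for var, levels in (
        ("age_band", cohort.AGE_BAND_LABELS),
        ("sex", cohort.SEXES),
    ):
        emp = groups["employed"]
        dis = groups["discontinued"]
        emp_lab = cohort.age_band_series(emp["age"]) if var == "age_band" else emp["sex"]
        dis_lab = cohort.age_band_series(dis["age"]) if var == "age_band" else dis["sex"]
        for level in levels:
            ne = int((emp_lab == level).sum())
            nd = int((dis_lab == level).sum())
            tot = ne + nd
            cat_rows.append(
                {
                    "variable": var,
                    "level": level,
                    "n_employed": ne,
                    "n_discontinued": nd,
                    "pct_employed": 100.0 * ne / tot if tot else np.nan,
                    "pct_discontinued": 100.0 * nd / tot if tot else np.nan,
                }
            )

    return GroupSummary(
        n_employed=len(groups["employed"]),
        n_discontinued=len(groups["discontinued"]),
        continuous=pd.DataFrame(cont_rows).set_index("variable"),
        categorical=pd.DataFrame(cat_rows).set_index(["variable", "level"]),
    )


def chi2_independence(table: np.ndarray) -> AssociationTest:
    """Pearson chi-squared test of independence (no continuity correction)."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return AssociationTest(float(res.statistic), float(res.dof), float(res.pvalue), "chi2")


def two_sample_t(x0, x1) -> AssociationTest:
    """Pooled-variance two-sample t-test on available cases."""
    x0 = np.asarray(pd.Series(x0).dropna(), dtype=float)
    x1 = np.asarray(pd.Series(x1).dropna(), dtype=float)
    if np.var(x0, ddof=1) == 0 and np.var(x1, ddof=1) == 0:
        raise ValueError(
            "both groups have zero variance; use an exact or rank-based test"
        )
    res = stats.ttest_ind(x0, x1, equal_var=True)
    return AssociationTest(
        float(res.statistic), float(len(x0) + len(x1) - 2), float(res.pvalue), "t"
    )


def cochran_armitage_trend(
    successes: Sequence[float],
    totals: Sequence[float],
    scores_: Sequence[float] | None = None,
) -> AssociationTest:
    """Cochran-Armitage test for a linear trend in proportions across
    ordered categories (default scores 0, 1, 2, ...)."""
    k = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    s = np.arange(len(k), dtype=float) if scores_ is None else np.asarray(scores_, float)
    N = n.sum()
    pbar = k.sum() / N
    sbar = (n * s).sum() / N
    num = ((s - sbar) * k).sum()
    var = pbar * (1 - pbar) * ((s - sbar) ** 2 * n).sum()
    z = num / np.sqrt(var)
    return AssociationTest(float(z), 1.0, float(2 * stats.norm.sf(abs(z))), "trend")


def test_association(scored: pd.DataFrame, variable: str) -> AssociationTest:
    """Dispatch the published comparison for one Table-1 variable.

    Categorical variables (sex, age band) get a chi-squared test on the
    group x level table; continuous variables get the pooled t-test;
    ``assessment_year`` gets a trend test on the proportion of patients with
    above-median illness duration per year.
    """
    y = resolve_outcome(scored)
    if variable in ("sex", "age_band"):
        labels = (
            cohort.age_band_series(scored["age"]) if variable == "age_band" else scored["sex"]
        )
        levels = cohort.AGE_BAND_LABELS if variable == "age_band" else cohort.SEXES
        table = [
            [int(((labels == lv) & (y == g)).sum()) for lv in levels] for g in (0, 1)
        ]
        return chi2_independence(np.asarray(table))
    if variable == "assessment_year":
        dur = scored["duration_illness"]
        ok = dur.notna()
        cut = dur[ok].median()
        years = sorted(scored.loc[ok, "assessment_year"].unique())
        k = [int(((scored["assessment_year"] == yr) & (dur > cut)).sum()) for yr in years]
        n = [int((ok & (scored["assessment_year"] == yr)).sum()) for yr in years]
        return cochran_armitage_trend(k, n, scores_=years)
    if variable in CONTINUOUS_VARIABLES:
        return two_sample_t(scored.loc[y == 0, variable], scored.loc[y == 1, variable])
    raise ValueError(f"unknown variable {variable!r}")
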