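"""Human-capital productivity losses stratified by sex and age band.

The loss attributed to one stratum is the product

    L = N x d x (m / 12) x f x y

of the number of patients N, the fraction d who had discontinued employment,
the median duration of illness m in months, the per-sex unemployment fraction
f (duration unemployed / duration ill, estimated from an external sample),
and the stratum's mean gross annual income y. Arithmetic is carried at full
floating precision; rounding to whole pounds happens only at display.

Per-person losses are reported on pooled groups: the sparse 18-21 band is
merged into 22-29 (per sex); every other band stands alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort

logger = logging.getLogger(__name__)

MONTHS_PER_YEAR = 12.0

#: Ordered pooled groups used for per-person losses and the extrapolation.
POOLED_GROUPS: tuple[str, ...] = ("18-29", "30-39", "40-49", "50-59", "60-64")


def pooled_group(age_band: str) -> str:
    """Map an age band onto its pooled reporting group (18-21 -> 18-29)."""
    if age_band in ("18-21", "22-29"):
        return "18-29"
    if age_band not in cohort.AGE_BAND_LABELS:
        raise ValueError(f"unknown age band {age_band!r}")
    return age_band


@dataclass(frozen=True)
class UnemploymentFraction:
    """Per-sex mean of (duration unemployed / duration ill) with its 95%
    t-interval. The interval is not truncated at zero: with few records and
    dispersed ratios the lower t-bound can be negative."""

    sex: str
    mean_fraction: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 records to form an interval")
        if not (self.ci_low <= self.mean_fraction <= self.ci_high):
            raise ValueError("interval must bracket the mean")


@dataclass(frozen=True)
class CostTable:
    """The stratified cost table: per-stratum rows, per-sex subtotals and
    per-patient averages, and the grand total."""

    rows: pd.DataFrame
    subtotals: pd.DataFrame
    total_loss: float
    total_n: int

    @property
    def loss_per_patient(self) -> float:
        return self.total_loss / self.total_n


def estimate_unemployment_fraction(
    sample: pd.DataFrame,
    sex: str,
    method: str = "mean_of_ratios",
) -> UnemploymentFraction:
    """Estimate the unemployment fraction for one sex from the external sample.

    ``mean_of_ratios`` (default): each record contributes its own ratio and
    the estimate is the sample mean with an exact t-interval,
    mean +/- t(n-1, 0.975) x SE. ``ratio_of_means`` divides the mean
    unemployment duration by the mean illness duration, with a delta-method
    standard error feeding the same t quantile.

    Records with zero illness duration are rejected with a logged diagnostic.
    """
    g = sample[sample["sex"] == sex]
    bad = g["duration_illness_months"] <= 0
    if bad.any():
        logger.warning(
            "rejected %d external record(s) with non-positive illness duration (rows %s)",
            int(bad.sum()),
            list(g.index[bad]),
        )
        g = g[~bad]
    n = len(g)
    if n < 2:
        raise ValueError(f"need >= 2 usable records for sex {sex!r}, have {n}")
    u = g["duration_unemployment_months"].to_numpy(float)
    d = g["duration_illness_months"].to_numpy(float)
    tq = stats.t.ppf(0.975, n - 1)
    if method == "mean_of_ratios":
        r = u / d
        mean = float(r.mean())
        se = float(r.std(ddof=1) / np.sqrt(n))
    elif method == "ratio_of_means":
        mean = float(u.mean() / d.mean())
        # delta method for a ratio of correlated means
        mu_u, mu_d = u.mean(), d.mean()
        var_u = u.var(ddof=1) / n
        var_d = d.var(ddof=1) / n
        cov = np.cov(u, d, ddof=1)[0, 1] / n
        se = float(
            abs(mu_u / mu_d)
            * np.sqrt(var_u / mu_u**2 + var_d / mu_d**2 - 2 * cov / (mu_u * mu_d))
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return UnemploymentFraction(sex, mean, mean - tq * se, mean + tq * se, n)


def stratum_loss(
    n: float, frac: float, months: float, fraction: float, income: float
) -> float:
    """The human-capital loss product for one stratum, at full precision."""
    for name, v in (("n", n), ("frac", frac), ("months", months),
                    ("fraction", fraction), ("income", income)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    return n * frac * (months / MONTHS_PER_YEAR) * fraction * income


def per_person_loss(losses: Sequence[float], ns: Sequence[float]) -> float:
    """Pooled-group loss per patient: sum of losses over sum of patients."""
    total_n = float(np.sum(ns))
    if total_n <= 0:
        raise ValueError("pooled group has no patients")
    return float(np.sum(losses)) / total_n


def _fraction_value(f) -> float:
    return f.mean_fraction if isinstance(f, UnemploymentFraction) else float(f)


def compute_cost_table(
    summaries: pd.DataFrame,
    economics: pd.DataFrame,
    fractions: Mapping[str, "UnemploymentFraction | float"],
) -> CostTable:
    """Assemble the stratified cost table.

    ``summaries`` carries one row per stratum (sex, age_band, n,
    frac_discontinued, median_illness_months); ``economics`` the per-stratum
    mean annual income; ``fractions`` the per-sex unemployment fraction.
    Raises if any stratum lacks an economics row.
    """
    econ = economics.set_index(["sex", "age_band"])
    rows = []
    for _, s in summaries.iterrows():
        key = (s["sex"], s["age_band"])
        if key not in econ.index:
            raise ValueError(f"no economics row for stratum {key}")
        income = float(econ.loc[key, "mean_annual_income"])
        f = _fraction_value(fractions[s["sex"]])
        loss = stratum_loss(
            s["n"], s["frac_discontinued"], s["median_illness_months"], f, income
        )
        rows.append(
            {
                "sex": s["sex"],
                "age_band": s["age_band"],
                "pooled_group": pooled_group(s["age_band"]),
                "n": float(s["n"]),
                "frac_discontinued": float(s["frac_discontinued"]),
                "median_illness_months": float(s["median_illness_months"]),
                "mean_annual_income": income,
                "loss": loss,
            }
        )
    frame = pd.DataFrame(rows)

    pooled = (
        frame.groupby(["sex", "pooled_group"], sort=False)
        .agg(pooled_n=("n", "sum"), pooled_loss=("loss", "sum"))
        .reset_index()
    )
    pooled["per_person_loss"] = pooled["pooled_loss"] / pooled["pooled_n"]
    frame = frame.merge(pooled, on=["sex", "pooled_group"], how="left")
    # mirror the published layout: the per-person figure sits on the pooled
    # group's anchor row (22-29 for the 18-29 pool), blank on 18-21
    frame.loc[frame["age_band"] == "18-21", "per_person_loss"] = np.nan

    subtotals = (
        frame.groupby("sex", sort=False)
        .agg(n=("n", "sum"), loss=("loss", "sum"))
        .reset_index()
    )
    subtotals["loss_per_patient"] = subtotals["loss"] / subtotals["n"]

    return CostTable(
        rows=frame,
        subtotals=subtotals.set_index("sex"),
        total_loss=float(frame["loss"].sum()),
        total_n=int(frame["n"].sum()),
    )


def summaries_from_cohort(
    scored: pd.DataFrame,
    include_other_in_denominator: bool = True,
) -> pd.DataFrame:
    """Derive the per-stratum summary table from patient records.

    N counts every eligible patient in the stratum (recorded status or not);
    the discontinued fraction is computed among patients with any recorded
    status, "other" included in the denominator by default (set
    ``include_other_in_denominator=False`` to restrict to the binary
    employed/discontinued set); the median illness duration uses available
    cases.
    """
    strata = cohort.stratify(scored)
    rows = []
    for (sex, band), g in strata.items():
        status = g["employment_status"]
        recorded = status.isin(cohort.EMPLOYMENT_STATUSES)
        if not include_other_in_denominator:
            recorded = status.isin(
                ("currently_employed",) + cohort.DISCONTINUED_STATUSES
            )
        denom = int(recorded.sum())
        disc = int(status.isin(cohort.DISCONTINUED_STATUSES).sum())
        dur = g["duration_illness"].dropna()
        rows.append(
            {
                "sex": sex,
                "age_band": band,
                "n": len(g),
                "frac_discontinued": disc / denom if denom else 0.0,
                "median_illness_months": float(dur.median()) if len(dur) else 0.0,
            }
        )
    return pd.DataFrame(rows)
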