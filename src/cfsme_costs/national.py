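"""Nationwide extrapolation of the cohort's productivity losses.

The annual access rate of a pooled sex x age group is the number of patients
seen, divided by the number of study years (four by default) and the
catchment (Primary Care Trust) population, expressed per 100,000 per year.
Multiplying by the UK population of the same group projects the annual number
of people who might access specialist services nationwide; multiplying again
by the group's per-person loss projects the annual national productivity
cost. Unrounded intermediates are carried throughout; display rounding is
confined to the report writer.

Two one-way sensitivity analyses re-run the whole pipeline with a single
parameter — the per-sex unemployment fraction, or the per-stratum
discontinued proportions — pinned to the ends of its 95% confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import costs as costs_mod
from .costs import CostTable, UnemploymentFraction, pooled_group

STUDY_YEARS = 4.0
PER = 100_000.0


@dataclass(frozen=True)
class AccessRate:
    """Annual users of specialist services per 100,000 catchment population."""

    sex: str
    pooled_group: str
    rate: float


@dataclass(frozen=True)
class NationalEstimate:
    """Per-group projected annual patients and costs, with sex/overall totals."""

    groups: pd.DataFrame
    sex_totals: pd.DataFrame
    total_patients: float
    total_cost: float


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    low_inputs: dict
    high_inputs: dict
    low_total: float
    high_total: float


def access_rate(n: float, years: float, catchment: float) -> float:
    """((n / years) / catchment) x 100,000, at full precision."""
    if years <= 0:
        raise ValueError("years must be positive")
    if catchment <= 0:
        raise ValueError("catchment population must be positive")
    if n < 0:
        raise ValueError("n must be nonnegative")
    return (n / years) / catchment * PER


def group_table(
    cost_table: CostTable,
    economics: pd.DataFrame,
    years: float = STUDY_YEARS,
) -> pd.DataFrame:
    """Pooled-group table joining patient counts, per-person losses,
    catchment and UK populations, and the access rate.

    Population cells of the 18-21 band are blank in the economics table;
    the 22-29 row's figures cover the pooled 18-29 group.
    """
    econ = economics.copy()
    econ["pooled_group"] = econ["age_band"].map(pooled_group)
    pops = (
        econ.groupby(["sex", "pooled_group"], sort=False)
        .agg(
            catchment=("pct_population", "sum"),
            uk_thousands=("uk_population_thousands", "sum"),
        )
        .reset_index()
    )
    grp = (
        cost_table.rows.groupby(["sex", "pooled_group"], sort=False)
        .agg(n=("n", "sum"), loss=("loss", "sum"))
        .reset_index()
    )
    grp["per_person_loss"] = grp["loss"] / grp["n"]
    merged = grp.merge(pops, on=["sex", "pooled_group"], how="left")
    missing = merged.loc[
        merged["catchment"].isna() | (merged["catchment"] <= 0), ["sex", "pooled_group"]
    ]
    if len(missing):
        raise ValueError(
            f"groups without catchment population: {missing.to_records(index=False).tolist()}"
        )
    merged["rate"] = [
        access_rate(n, years, c) for n, c in zip(merged["n"], merged["catchment"])
    ]
    return merged


def national_projection(groups: pd.DataFrame) -> NationalEstimate:
    """Project annual UK patients and costs from the pooled-group table.

    patients = rate x UK population / 100,000 (populations arrive in
    thousands and are converted exactly); cost = patients x per-person loss.
    """
    need = {"sex", "pooled_group", "rate", "uk_thousands", "per_person_loss"}
    missing = need - set(groups.columns)
    if missing:
        raise ValueError(f"group table missing columns: {sorted(missing)}")
    out = groups.copy()
    if out["uk_thousands"].isna().any():
        bad = out.loc[out["uk_thousands"].isna(), ["sex", "pooled_group"]]
        raise ValueError(
            f"groups without UK population: {bad.to_records(index=False).tolist()}"
        )
    out["projected_patients"] = out["rate"] * out["uk_thousands"] * 1000.0 / PER
    out["projected_cost"] = out["projected_patients"] * out["per_person_loss"]
    sex_totals = (
        out.groupby("sex", sort=False)
        .agg(
            n=("n", "sum"),
            catchment=("catchment", "sum"),
            uk_thousands=("uk_thousands", "sum"),
            projected_patients=("projected_patients", "sum"),
            projected_cost=("projected_cost", "sum"),
        )
    )
    return NationalEstimate(
        groups=out,
        sex_totals=sex_totals,
        total_patients=float(out["projected_patients"].sum()),
        total_cost=float(out["projected_cost"].sum()),
    )


def project_national(
    summaries: pd.DataFrame,
    economics: pd.DataFrame,
    fractions: Mapping[str, "UnemploymentFraction | float"],
    years: float = STUDY_YEARS,
) -> tuple[CostTable, pd.DataFrame, NationalEstimate]:
    """Run the full pipeline: cost table -> pooled groups -> UK projection."""
    table = costs_mod.compute_cost_table(summaries, economics, fractions)
    groups = group_table(table, economics, years)
    return table, groups, national_projection(groups)


# ---------------------------------------------------------------------------
# one-way sensitivity analyses


def _fraction_bounds(
    fractions: Mapping[str, "UnemploymentFraction | float"],
    bounds: Mapping[str, tuple[float, float]] | None,
) -> dict[str, tuple[float, float]]:
    out = {}
    for sex, f in fractions.items():
        if bounds is not None and sex in bounds:
            lo, hi = bounds[sex]
        elif isinstance(f, UnemploymentFraction):
            lo, hi = f.ci_low, f.ci_high
        else:
            raise ValueError(
                f"no interval available for sex {sex!r}: pass explicit bounds"
            )
        if lo > hi:
            raise ValueError(f"bounds for {sex!r} must satisfy low <= high")
        out[sex] = (lo, hi)
    return out


def sensitivity_one_way(
    summaries: pd.DataFrame,
    economics: pd.DataFrame,
    fractions: Mapping[str, "UnemploymentFraction | float"],
    parameter: str,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    years: float = STUDY_YEARS,
    joint: bool = True,
) -> SensitivityResult:
    """Re-run the national projection at the low and high ends of one
    parameter's 95% interval, everything else held fixed.

    ``unemployment_fraction`` pins both sexes' fractions to the interval
    bounds (from ``bounds`` or the fractions' own intervals).
    ``discontinued_proportion`` replaces each stratum's discontinued
    proportion with its Wilson 95% bound; with ``joint=False`` the strata are
    instead rescaled by the pooled per-sex proportion's Wilson bounds.
    """
    if parameter == "unemployment_fraction":
        bnds = _fraction_bounds(fractions, bounds)
        for sex, (lo, hi) in bnds.items():
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError(f"fraction bounds for {sex!r} outside [0, 1]")
        low_fr = {sex: lo for sex, (lo, hi) in bnds.items()}
        high_fr = {sex: hi for sex, (lo, hi) in bnds.items()}
        *_, low = project_national(summaries, economics, low_fr, years)
        *_, high = project_national(summaries, economics, high_fr, years)
        return SensitivityResult(
            parameter, low_fr, high_fr, low.total_cost, high.total_cost
        )

    if parameter == "discontinued_proportion":
        low_sum = summaries.copy()
        high_sum = summaries.copy()
        if joint:
            k = summaries["frac_discontinued"] * summaries["n"]
            lo, hi = proportion_confint(k, summaries["n"], method="wilson")
            low_sum["frac_discontinued"] = lo
            high_sum["frac_discontinued"] = hi
        else:
            for sex in summaries["sex"].unique():
                m = summaries["sex"] == sex
                ksum = float((summaries.loc[m, "frac_discontinued"] * summaries.loc[m, "n"]).sum())
                nsum = float(summaries.loc[m, "n"].sum())
                lo, hi = proportion_confint(ksum, nsum, method="wilson")
                p = ksum / nsum
                low_sum.loc[m, "frac_discontinued"] = (
                    summaries.loc[m, "frac_discontinued"] * (lo / p)
                )
                high_sum.loc[m, "frac_discontinued"] = (
                    summaries.loc[m, "frac_discontinued"] * (hi / p)
                ).clip(upper=1.0)
        *_, low = project_national(low_sum, economics, fractions, years)
        *_, high = project_national(high_sum, economics, fractions, years)
        return SensitivityResult(
            parameter,
            {"frac_discontinued": "wilson 95% low"},
            {"frac_discontinued": "wilson 95% high"},
            low.total_cost,
            high.total_cost,
        )

    raise ValueError(f"unknown sensitivity parameter {parameter!r}")


# ---------------------------------------------------------------------------
# reporting


def _table3_frame(cost_table: CostTable, estimate: NationalEstimate) -> pd.DataFrame:
    left = cost_table.rows.copy()
    right = estimate.groups.set_index(["sex", "pooled_group"])
    anchor = left["age_band"].where(left["age_band"] != "18-21", None).notna()
    cols = {
        "catchment": "population_in_pcts",
        "rate": "access_rate_per_100k",
        "uk_thousands": "uk_population_thousands",
        "projected_patients": "uk_annual_patients",
        "projected_cost": "uk_annual_cost",
    }
    for src, dst in cols.items():
        left[dst] = [
            right.loc[(s, g), src] if a else np.nan
            for s, g, a in zip(left["sex"], left["pooled_group"], anchor)
        ]
    return left


def render_report(
    cost_table: CostTable,
    estimate: NationalEstimate,
    sensitivities: Sequence[SensitivityResult],
    out_dir,
) -> dict[str, Path]:
    """Write the stratified table (CSV), a plain-text narrative summary, and
    a machine-readable JSON of every headline figure.

    Output is deterministic: identical inputs render byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    table = _table3_frame(cost_table, estimate)
    paths["table"] = out / "cost_table.csv"
    table.to_csv(paths["table"], index=False, float_format="%.6f")

    headline = {
        "total_loss_gbp": round(cost_table.total_loss, 2),
        "loss_per_patient_gbp": round(cost_table.loss_per_patient, 2),
        "subtotals": {
            sex: {
                "loss_gbp": round(float(row["loss"]), 2),
                "loss_per_patient_gbp": round(float(row["loss_per_patient"]), 2),
            }
            for sex, row in cost_table.subtotals.iterrows()
        },
        "uk_annual_patients": round(estimate.total_patients, 1),
        "uk_annual_cost_gbp": round(estimate.total_cost, 2),
        "sensitivity": [
            {
                "parameter": s.parameter,
                "low_total_gbp": round(s.low_total, 2),
                "high_total_gbp": round(s.high_total, 2),
            }
            for s in sensitivities
        ],
    }
    paths["json"] = out / "results.json"
    paths["json"].write_text(json.dumps(headline, indent=2, sort_keys=True) + "\n")

    lines = [
        "Productivity costs of CFS/ME prior to specialist assessment",
        "==========================================================",
        "",
        f"Cohort loss: GBP {cost_table.total_loss:,.0f} "
        f"({cost_table.total_n} patients, GBP {cost_table.loss_per_patient:,.0f} per patient)",
    ]
    for sex, row in cost_table.subtotals.iterrows():
        lines.append(
            f"  {sex}: GBP {row['loss']:,.0f} "
            f"(GBP {row['loss_per_patient']:,.0f} per patient)"
        )
    lines += [
        "",
        f"Projected annual UK patients accessing services: {estimate.total_patients:,.0f}",
        f"Projected annual UK productivity cost: GBP {estimate.total_cost:,.0f}",
    ]
    if sensitivities:
        lines.append("")
        lines.append("One-way sensitivity analyses (95% CI bounds):")
        for s in sensitivities:
            lines.append(
                f"  {s.parameter}: GBP {s.low_total:,.0f} - GBP {s.high_total:,.0f}"
            )
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
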